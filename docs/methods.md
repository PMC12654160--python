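# Methods

This note documents the models, numerical choices and limitations behind
`soilpem`, in the order the pipeline runs them.

## Study design and data model

The package models a long-term fertilization trial in a rice–wheat
rotation with five treatments (CK, OPT, OPTN, OPTP, OPTM) in a
randomized complete block design with four replicates. Canonical on-disk
format is tab-separated text: OTU count tables (features × samples, with
`domain` and `taxonomy` columns; phylum parsed from the `p__` token),
and per-sample tables for soil chemistry, bioavailable P fractions
(CaCl₂-P, Citrate-P, Enzyme-P, HCl-P, mg kg⁻¹) and enzyme activities
(BG, CBH, NAG, LAP, ALP, nmol h⁻¹ g⁻¹ dry soil). Validation treats
missing samples and missing numeric cells as fatal; an unbalanced
replicate design is advisory only, since the analyses tolerate mild
imbalance (Duncan's test then uses the harmonic mean of group sizes).
Block (replicate) is not modelled as a factor: all group comparisons are
one-way ANOVA across treatments.

## Synthetic study generator

The generator's defaults are the study conditions, so that every
downstream stage can be exercised and calibrated without field data.

- **Soil chemistry.** Treatment means and standard errors are the
  published values; the reported ± values are standard errors with
  n = 4, so plot-level SD = SE·√4. pH is drawn normally; concentrations
  are drawn log-normally matched to (mean, SD). The log-normal choice is
  deliberate: several published rows (e.g. available P under CK,
  5.77 ± SE 5.84) have SDs comparable to their means, and a clipped
  normal would bias the Monte-Carlo mean upward, whereas the matched
  log-normal is non-negative and mean-exact by construction.
- **Enzyme activities and P fractions.** Log-normal with configured
  arithmetic means and CVs of 8% and 10% respectively (typical plot-level
  assay variability). OPTM means for BG, CBH, NAG are the OPT means
  scaled by the published +22.74%, +40.90%, +18.09%; P-fraction means
  encode the published Citrate-P endpoints (17.70 → 31.83 mg kg⁻¹) and
  the OPTM-vs-OPT contrasts (+62.64% Enzyme-P, +11.24% Citrate-P,
  +9.49% HCl-P). Where the published range of a variable and its percent
  contrasts cannot both hold (Enzyme-P), the percent contrasts win and
  the range is treated as advisory. LAP and ALP means decline under every
  fertilized regime, and the implied stoichiometric vector angles span
  ≈22–25° with CK highest and OPTP lowest, matching the reported
  ordering. Because the log-normals are mean-parametrized, empirical
  treatment-mean ratios converge to the configured contrast ratios
  (verified at 200 replicates within 2%).
- **OTU tables.** Per domain (bacteria/fungi/archaea; default richness
  600/240/80 to approximate the observed 65/26/9% node split), a
  log-normal base composition is perturbed by a per-treatment multiplier
  on a responsive 25% subset of taxa, then counts are drawn
  Dirichlet-multinomial (concentration 200) for realistic
  overdispersion. `spike_network_structure` overwrites chosen disjoint
  taxon groups with monotone transforms of a shared latent factor, giving
  within-group Spearman correlations centred at a stated strength and
  cross-group correlations centred at zero — a ground truth for the
  network stage.
- **Yield.** yield = a + b₁·(SOM−c₁) + b₂·(AP−c₂) +
  b₃·(SOM−c₁)(AP−c₂) + b₄·(H−c₃) + ε with H the bacterial Shannon
  index and ε Gaussian. No per-plot yields are published, so the scale is
  unitless; the default coefficients (0.15, 0.010, 0.004, 0.30, noise SD
  0.25) give the interaction enough signal to be recovered with power
  > 0.8 at the design's n = 20, which is the property the generator is
  required to have.

What the generator does **not** emulate: spatial field structure,
temporal dynamics over the 16 years, sequencing depth artefacts,
compositional coupling between taxa and chemistry beyond the treatment
means. Passing tests therefore demonstrate correctness of the
computational chain under the published effect sizes, not re-derivation
of the field results themselves.

## Enzyme stoichiometry

Fluorescence → activity follows the standard fluorometric formulation:
net signal = assay − blank − quench·negative-control; the emission
coefficient (units nmol⁻¹) comes from the buffer reference standard and
the quench coefficient from the homogenate standard over the reference
standard; product nmol are scaled by incubation time and dry soil per
well. Negative net fluorescence is floored at zero (and logged) rather
than dropped. Exact plate constants are configuration, not hard-coded.

Ratios use natural logarithms of raw activities in nmol h⁻¹ g⁻¹. A sum
≤ 1 makes a log-ratio sign-unstable, so such samples are flagged and
excluded from group means with a logged warning instead of being
silently transformed. The vector angle is the two-argument arctangent of
the point (x, y) measured from the x-axis — i.e. arctan(y/x) for x > 0 —
which is the only convention under which "angle > 45° ⇒ P limitation"
holds; exactly 45° is classified "balanced". Per-sample ratios are
computed first and then averaged within treatments (not ratios of
treatment means).

## Group statistics

Duncan's multiple range test computes least significant ranges
R_p = q(α_p, p, df)·√(MSE/n_h) with α_p = 1−(1−α)^(p−1) from the
studentized-range distribution, spans evaluated longest-first so that a
stretch enclosed in a homogeneous range can never be declared
significant. That protection makes non-significance interval-closed over
the descending mean order, so letters are maximal homogeneous intervals
(ties in means broken by input order, deterministic). For published
mean ± SE tables the pooled error square is reconstructed as
MSE = mean(n·SE²) under homoscedasticity — an approximation, adequate to
reproduce the qualitative letter patterns (top/bottom isolation) but not
guaranteed to replicate every published letter, which depends on raw
data.

## Community metrics

Shannon (nats) and bias-corrected Chao1 follow the standard formulas;
Bray–Curtis uses raw counts as relative abundances without rarefaction by
default (seeded rarefaction to minimum depth is available). NMDS uses a
seeded SMACOF optimizer (non-metric, random starts, best of 4 inits) and
reports normalized Kruskal stress-1 in [0, 1]. The ordination distance is
Bray–Curtis throughout: no phylogenetic tree is part of the data model,
so UniFrac variants are out of scope by design.

## Co-occurrence networks

All three domains are pooled into one correlation matrix before
thresholding; a per-domain mode exists. The screen keeps taxon pairs with
|Spearman ρ| > 0.75 and raw two-sided p < 0.01 (t-approximation with tie
handling); signed edges are kept with ρ as weight, and a
`positive_only` switch restores the literal positive-threshold reading.
No multiple-testing correction is applied by default, matching the raw
thresholds convention of the method. A prevalence filter (present in
≥ 20% of samples) avoids rank-tie pathologies; constant taxa are excluded
with a warning. Modules come from seeded Louvain (greedy multilevel)
optimization on the unweighted graph — modularity values are
algorithm-dependent, so the algorithm and seed are fixed and recorded.
Zi is the within-module degree z-score (module SD 0 ⇒ Zi = 0); Pi =
1 − Σ_s (k_is/k_i)² with Pi = 0 for isolated nodes; role thresholds are
Zi > 2.5 and Pi > 0.62 with network-hub precedence. Per-treatment
subnetworks are induced on taxa with nonzero total count in that
treatment's samples (presence-induction); path metrics are computed on
the largest connected component, and local clustering counts degree ≤ 1
nodes as zero.

## Associations

The Mantel statistic correlates strictly-lower-triangle entries
(Pearson default, Spearman available); the null permutes rows and
columns of the second matrix simultaneously, and p is one-sided
"greater", (1 + #{r_perm ≥ r_obs})/(n_perm + 1). For n ≤ 7 an exhaustive
mode enumerates all n! permutations and reports the exact fraction.
Community distance is Bray–Curtis; environmental distance is Euclidean
on z-scored variables. The correlation panel is Pearson by default with
stars at p < 0.05/0.01/0.001, pairwise deletion of missing pairs, and
explicit flags for undefined (constant-column) cells. The yield GLM is
Gaussian-identity OLS on centred SOM, AP and their product; centring
leaves the interaction coefficient unchanged (asserted numerically) and
rank deficiency aborts with condition diagnostics.

## Latent models

PLS-PM is implemented in-repo: indicators standardized, outer weights
initialized equal, alternating inner approximation (centroid scheme by
default — signs of latent correlations along inner links; factorial
available) and mode-A outer update (indicator–proxy correlations,
normalized, sign-anchored to the previous iterate) until the largest
weight change < 10⁻⁷ (cap 300 iterations, non-convergence is fatal with
a trace). Latent scores are standardized and oriented to correlate
positively with each block's first indicator; path coefficients are OLS
of each endogenous latent on its predecessors; GoF =
√(mean communality × mean R²). With a single indicator per block the path
coefficient reduces exactly to the indicators' Pearson correlation,
which anchors the implementation. Recovery on a known latent chain is
attenuated by composite reliability (≈ 4% with six indicators loading
0.9), which is inherent to composite-based estimation, not an
implementation artefact. Bootstrap significance resamples rows
(bootstrap_n seeded draws), refits, and reports two-sided percentile
p-values of zero with 95% percentile intervals; > 10% failed resamples
aborts. The default block structure — fertilization dose → {P fractions,
enzymes, community} → yield — is one reading of such studies' path
diagrams and is fully configurable.

Random-forest importance is %IncMSE: out-of-bag MSE increase under
single-predictor permutation, computed with explicit bagging over
scikit-learn regression trees (mtry = ⌊p/3⌋) so OOB membership is exact
and seeded. Significance refits the forest on response-permuted data and
locates the observed %IncMSE in its null, p = (1 + #{null ≥ obs})/(n_perm
+ 1). Because permutation p-values are discrete, calibration checks use
p ≤ 0.05 with n_perm chosen so that 0.05·(n_perm + 1) is an integer.

## Pipeline and reproducibility

`run_all` derives one seed per stochastic stage from the global seed by a
fixed per-stage offset (seed·1000 + stage constant, mod 2³¹−1), so adding
a stage never shifts another stage's random stream; identical config and
seed give byte-identical outputs. A failing stage aborts with its name
while retaining earlier outputs; the manifest records version, seeds,
thresholds and completed stages.

## Problem sizes in tests and the acceptance script

Statistical calibration uses 100–200 simulations per procedure (Mantel:
n = 15 matrices, 199 permutations; random forest: n = 20, 3 predictors,
40 trees, 39 response permutations; PLS-PM bootstrap: n = 100, 99
resamples), and path recovery uses n = 500 with six indicators per block
averaged over three replicates — sizes chosen to estimate a 5% rejection
rate to within ±0.03 while keeping the suite quick on a single CPU.
Generator-fidelity checks use 200 replicates per treatment, where the
standard error of a mean ratio at 8–10% CV is well under the 2%
tolerance.

## Known limitations

- The published network (823 nodes, 2698 edges, Q = 0.596) cannot be
  reproduced without the study's sequencing data; the network stage is
  validated on spiked ground truth and closed-form oracles instead.
- Duncan letters reconstructed from printed summaries approximate, not
  replicate, letters computed from raw data.
- PLS-PM path estimates carry composite attenuation; comparisons across
  models with different indicator counts should use the same blocks.
- Compositionality of OTU relative abundances is not corrected in the
  correlation screen (no SparCC/SPIEC-EASI); this mirrors the method
  being implemented.
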