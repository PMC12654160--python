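"""Seeded synthetic study generator.

Emulates the 5-treatment x 4-replicate fertilization design: OTU count
tables for bacteria, fungi and archaea with treatment-structured
compositional shifts, soil chemistry centred on the published treatment
means, enzyme activities and P fractions whose treatment-mean ratios
encode the published percent contrasts, and a yield variable driven by
SOM, AP, their interaction and microbial diversity.

Activities are drawn log-normally but parametrized so the *arithmetic*
per-treatment mean equals the configured mean; empirical mean ratios
between treatments therefore converge to the configured contrast ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import reference as ref
from .core import (DOMAINS, EnzymeActivityTable, FeatureTable, PFractionTable,
                   SampleMetadata, SoilChemistryTable, StudyDataset,
                   ValidationError)
from .diversity import shannon


def _default_richness() -> dict[str, int]:
    # Domain richness roughly matching the observed 65/26/9% node split.
    return {"bacteria": 600, "fungi": 240, "archaea": 80}


def _default_depth() -> dict[str, int]:
    return {"bacteria": 20000, "fungi": 10000, "archaea": 4000}


def _default_multipliers() -> dict[str, float]:
    # Compositional boost applied to the responsive taxon subset; straw
    # returning (OPTM) perturbs the community most.
    return {"CK": 1.0, "OPT": 1.5, "OPTN": 1.6, "OPTP": 1.8, "OPTM": 2.2}


@dataclass
class YieldModel:
    """Linear yield model: SOM and AP main effects, their interaction,
    and a diversity term, on centred predictors, plus Gaussian noise.
    Yield is unitless by default (no per-plot yields are published)."""

    intercept: float = 5.0
    b_som: float = 0.15
    b_ap: float = 0.010
    b_interaction: float = 0.004
    b_diversity: float = 0.30
    som_center: float = 27.0
    ap_center: float = 50.0
    diversity_center: float = 5.5
    noise_sd: float = 0.25


@dataclass
class GeneratorConfig:
    n_replicates: int = ref.N_REPLICATES
    treatments: tuple[str, ...] = ref.TREATMENTS
    soil_chemistry: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: ref.SOIL_CHEMISTRY)
    enzyme_means: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: ref.ENZYME_MEANS)
    enzyme_cv: float = ref.ENZYME_CV
    p_fraction_means: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: ref.P_FRACTION_MEANS)
    p_fraction_cv: float = ref.P_FRACTION_CV
    richness: Mapping[str, int] = field(default_factory=_default_richness)
    depth: Mapping[str, int] = field(default_factory=_default_depth)
    responsive_fraction: float = 0.25
    multipliers: Mapping[str, float] = field(default_factory=_default_multipliers)
    concentration: float = 200.0   # Dirichlet-multinomial overdispersion
    yield_model: YieldModel = field(default_factory=YieldModel)
    seed: int = 0

    def validate(self) -> None:
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be positive")
        if self.enzyme_cv <= 0 or self.p_fraction_cv <= 0:
            raise ValidationError("dispersions must be positive")
        if any(m <= 0 for m in self.multipliers.values()):
            raise ValidationError("treatment multipliers must be positive")
        if self.concentration <= 0:
            raise ValidationError("concentration must be positive")


# Table 1 reports means +/- standard errors with n = 4, so the plot-level
# SD is SE * sqrt(4).
_SE_TO_SD = 2.0

_PHYLA = {
    "bacteria": ["Proteobacteria", "Acidobacteriota", "Chloroflexi",
                 "Actinobacteriota", "Bacteroidota", "Nitrospirota"],
    "fungi": ["Ascomycota", "Basidiomycota", "Mortierellomycota",
              "Rozellomycota"],
    "archaea": ["Crenarchaeota", "Euryarchaeota", "Halobacterota"],
}


def _make_metadata(config: GeneratorConfig) -> SampleMetadata:
    records = [(f"{t}_{r}", t, r)
               for t in config.treatments
               for r in range(1, config.n_replicates + 1)]
    return SampleMetadata.from_records(records)


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given arithmetic mean and CV."""
    sigma2 = np.log1p(cv ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def _sample_activity_table(config, meta, rng, means, cv, columns) -> pd.DataFrame:
    data = {}
    treatments = meta.treatments
    for col in columns:
        vals = np.empty(len(meta.sample_ids))
        for i, t in enumerate(treatments):
            mu, sigma = _lognormal_params(means[col][t], cv)
            vals[i] = rng.lognormal(mu, sigma)
        data[col] = vals
    return pd.DataFrame(data, index=meta.sample_ids)


def _sample_chemistry_table(config, meta, rng) -> pd.DataFrame:
    """pH is drawn normally; concentrations log-normally matched to the
    configured (mean, SD) so they stay non-negative without biasing the
    mean (several printed rows, e.g. unfertilized available P, have SDs
    comparable to their means)."""
    data = {}
    treatments = meta.treatments
    for var, per_t in config.soil_chemistry.items():
        vals = np.empty(len(meta.sample_ids))
        for i, t in enumerate(treatments):
            mean, se = per_t[t]
            sd = se * _SE_TO_SD
            if var == "pH":
                vals[i] = rng.normal(mean, sd)
            else:
                mu, sigma = _lognormal_params(mean, sd / mean)
                vals[i] = rng.lognormal(mu, sigma)
        if var == "pH":
            vals = np.clip(vals, 0.01, 13.99)
        data[var] = vals
    return pd.DataFrame(data, index=meta.sample_ids)


def _make_feature_table(domain: str, config: GeneratorConfig,
                        meta: SampleMetadata, rng: np.random.Generator
                        ) -> FeatureTable:
    n_taxa = int(config.richness[domain])
    depth = int(config.depth[domain])
    base = rng.lognormal(0.0, 1.2, size=n_taxa)
    base /= base.sum()
    n_resp = int(round(config.responsive_fraction * n_taxa))
    responsive = rng.choice(n_taxa, size=n_resp, replace=False)
    phyla = rng.choice(_PHYLA[domain], size=n_taxa)
    prefix = {"bacteria": "b", "fungi": "f", "archaea": "a"}[domain]
    feature_ids = [f"OTU_{prefix}{i:04d}" for i in range(n_taxa)]
    taxonomy = pd.Series(
        [f"k__{domain};p__{ph};g__g{i}" for i, ph in enumerate(phyla)],
        index=feature_ids)
    counts = np.zeros((n_taxa, len(meta.sample_ids)), dtype=np.int64)
    for j, (sid, t) in enumerate(zip(meta.sample_ids, meta.treatments)):
        p = base.copy()
        p[responsive] *= config.multipliers[t]
        p /= p.sum()
        comp = rng.dirichlet(p * config.concentration)
        counts[:, j] = rng.multinomial(depth, comp)
    df = pd.DataFrame(counts, index=feature_ids, columns=meta.sample_ids)
    return FeatureTable(df, pd.Series(domain, index=feature_ids), taxonomy)


def generate_dataset(config: GeneratorConfig | None = None) -> StudyDataset:
    """Generate a full synthetic study from a seeded configuration."""
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    meta = _make_metadata(config)

    features = {dom: _make_feature_table(dom, config, meta, rng)
                for dom in DOMAINS}
    chem = _sample_chemistry_table(config, meta, rng)
    enz = _sample_activity_table(config, meta, rng, config.enzyme_means,
                                 config.enzyme_cv, list(config.enzyme_means))
    pfrac = _sample_activity_table(config, meta, rng, config.p_fraction_means,
                                   config.p_fraction_cv,
                                   list(config.p_fraction_means))

    ym = config.yield_model
    div = np.array([shannon(features["bacteria"].counts[s].to_numpy())
                    for s in meta.sample_ids])
    som_c = chem["SOM"].to_numpy() - ym.som_center
    ap_c = chem["AP"].to_numpy() - ym.ap_center
    yld = (ym.intercept + ym.b_som * som_c + ym.b_ap * ap_c
           + ym.b_interaction * som_c * ap_c
           + ym.b_diversity * (div - ym.diversity_center)
           + rng.normal(0.0, ym.noise_sd, size=len(som_c)))
    chem["yield"] = np.clip(yld, 0.0, None)

    return StudyDataset(
        metadata=meta,
        features=features,
        soil_chemistry=SoilChemistryTable(chem),
        p_fractions=PFractionTable(pfrac),
        enzymes=EnzymeActivityTable(enz),
    )


def spike_network_structure(table: FeatureTable,
                            module_spec: Sequence[Sequence[str]],
                            strength: float,
                            seed: int = 0) -> FeatureTable:
    """Overwrite counts of disjoint taxon groups with a shared latent driver.

    Each group gets its own per-sample latent factor; member abundances are
    monotone transforms of ``sqrt(strength) * latent + sqrt(1-strength) *
    noise``, so within-group pairwise Spearman correlations are centred at
    ``strength`` and across-group correlations at zero.
    """
    if not 0.0 <= strength <= 1.0:
        raise ValidationError("strength must be in [0, 1]")
    seen: set[str] = set()
    for group in module_spec:
        overlap = seen & set(group)
        if overlap:
            raise ValidationError(f"overlapping spike groups: {sorted(overlap)}")
        seen |= set(group)
    missing = seen - set(table.feature_ids)
    if missing:
        raise ValidationError(f"spike groups name unknown features: {sorted(missing)}")

    rng = np.random.default_rng(seed)
    counts = table.counts.copy()
    n = counts.shape[1]
    a = np.sqrt(strength)
    b = np.sqrt(1.0 - strength)
    for group in module_spec:
        latent = rng.standard_normal(n)
        for fid in group:
            eps = rng.standard_normal(n)
            x = a * latent + b * eps
            counts.loc[fid] = np.round(np.exp(np.log(50.0) + 0.8 * x)).astype(int)
    return FeatureTable(counts, table.domain.copy(), table.taxonomy.copy())
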