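"""PLS path modelling of yield drivers plus random-forest importance.

The default latent structure routes fertilization dose through P
fractions, enzyme activities and the microbial community to yield.
"""

import soilpem as sp
from soilpem.pipeline import _latent_indicator_table

dataset = sp.generate_dataset(sp.GeneratorConfig(
    seed=42, richness={"bacteria": 60, "fungi": 30, "archaea": 15}))
data = _latent_indicator_table(dataset, {})

spec = sp.default_plspm_spec()
spec.bootstrap_n = 199
boot = sp.plspm_bootstrap(data, spec)
print("PLS-PM path coefficients (bootstrap p):")
print(boot.paths.round(3).to_string(index=False))
model = sp.plspm_fit(data, spec)
print(f"\nGoF = {model.gof:.3f}; R2 = "
      + ", ".join(f"{k}: {v:.2f}" for k, v in model.r_squared.items()))

chem = dataset.soil_chemistry.data
predictors = chem[["SOM", "AP", "TN", "TP", "pH"]].join(
    dataset.p_fractions.data)
rf = sp.rf_importance(predictors, chem["yield"],
                      n_trees=500, n_perm=99, seed=0)
print("\nRandom-forest %IncMSE for yield "
      "(soil properties and P fractions; permutation p):")
print(rf.table.round(3))
# Positive %IncMSE means permuting that predictor degrades out-of-bag
# prediction; p locates the observed value in a response-permutation null.
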