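"""Mantel tests, the taxa-environment correlation panel, and the yield GLM."""

import soilpem as sp
from soilpem.association import environment_distance

dataset = sp.generate_dataset(sp.GeneratorConfig(seed=42))
chem = dataset.soil_chemistry.data
env = chem.drop(columns="yield").join(dataset.p_fractions.data)

community = sp.bray_curtis_matrix(dataset.features["bacteria"])
res = sp.mantel(community, environment_distance(env), n_perm=999, seed=0,
                exhaustive=False)
print(f"Mantel (bacteria ~ environment): r = {res.r:.3f}, p = {res.p:.3f}")
# r measures how well between-sample community dissimilarity tracks
# environmental distance; p is the one-sided permutation probability.

panel = sp.correlation_panel(dataset.p_fractions.data,
                             chem[["SOM", "AP", "yield"]])
print("\nP fractions vs chemistry/yield:")
print(panel.round(3).to_string(index=False))

glm = sp.yield_glm(chem["yield"], chem["SOM"], chem["AP"])
print("\nYield GLM (centred predictors):")
print(glm.round(4))
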