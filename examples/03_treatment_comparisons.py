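"""One-way ANOVA with Duncan's multiple range letters and percent changes.

Re-letters the published available-P row from its printed means and
standard errors (n = 4), then compares a synthetic SOM column from raw
replicate values.
"""

import soilpem as sp
from soilpem import reference as ref

labels = list(ref.TREATMENTS)
means = [ref.SOIL_CHEMISTRY["AP"][t][0] for t in labels]
ses = [ref.SOIL_CHEMISTRY["AP"][t][1] for t in labels]
res = sp.duncan_from_summary(labels, means, ses, [4] * 5)
print("Available P, re-lettered from printed summaries:")
print(res.table.round(2))
# OPTP stands alone at the top ('a'); the unfertilized control is alone
# at the bottom - the published pattern.

dataset = sp.generate_dataset(sp.GeneratorConfig(seed=42))
som = dataset.soil_chemistry.data["SOM"]
tab = sp.treatment_summary(som.to_numpy(),
                           dataset.metadata.treatments.to_numpy())
print("\nSynthetic SOM with percent change vs control:")
print(tab.round(2))

print("\nCitrate-P worked example:",
      f"{sp.percent_change(31.83, 17.70):.2f}% increase")
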