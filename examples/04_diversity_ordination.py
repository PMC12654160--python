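"""Alpha diversity (Shannon, Chao1) and Bray-Curtis NMDS ordination."""

import soilpem as sp

dataset = sp.generate_dataset(sp.GeneratorConfig(seed=42))
bacteria = dataset.features["bacteria"]

alpha = sp.alpha_diversity_table(bacteria)
print("Per-sample alpha diversity (bacteria):")
print(alpha.groupby(dataset.metadata.treatments).mean().round(2))

dist = sp.bray_curtis_matrix(bacteria)
ordination = sp.nmds(dist, k=2, seed=0)
print(f"\nNMDS stress = {ordination.stress:.4f} "
      f"(converged: {ordination.converged})")
print(ordination.coordinates.head(5).round(3))
# Low stress (< ~0.2) means the 2-D configuration preserves the rank
# order of community dissimilarities well.
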