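"""Generate a study-shaped synthetic dataset and look at its structure.

Builds a taxonomy of 80 genera (~290 species) under one beetle family,
draws ~66 softmax rows per species from the Dirichlet confidence model and
prints the basic shape of the result.
"""

import numpy as np

from taxback import SimulationConfig, simulate_dataset

config = SimulationConfig(seed=1)
taxonomy, specimens, matrix, latent = simulate_dataset(config)

genus_sizes = [taxonomy.genus_size(s) for s in taxonomy.species]
print(f"species: {taxonomy.n_species}, genera: {len(set(taxonomy.lineage_at_rank('genus')))}")
print(f"congeners per species: mean {np.mean(genus_sizes):.2f}, max {max(genus_sizes)}")
print(f"images: {matrix.n_images}; every row sums to 1: "
      f"{np.allclose(matrix.values.sum(axis=1), 1.0)}")
print(f"mean top-1 confidence: {matrix.values.max(axis=1).mean():.3f}")
print(f"mean latent correctness propensity: {latent['p'].mean():.3f}")

# The top-1 confidence is the classifier's highest softmax value per image;
# the latent propensity is the generative probability that the confidence
# mass was centred on the true species rather than on a congener.
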