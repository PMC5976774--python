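"""Inspect the automatic contrast-strength selection machinery.

Fits cPCA across the default grid (alpha = 0 plus 40 log-spaced values in
[0.1, 1000]), clusters the resulting 2-d subspaces by their
principal-angle cosine-product affinity, and prints the clusters and the
medoid alpha representing each one.
"""

import numpy as np

from cpca import auto_cpca
from cpca.synthetic import make_subgroup_scenario

scenario = make_subgroup_scenario(seed=0)
results, spectrum = auto_cpca(
    scenario.target, scenario.background, k=2, n_medoids=4,
    return_spectrum=True,
)

print(f"alpha grid: {len(spectrum.alphas)} values "
      f"({spectrum.alphas[0]:g} ... {spectrum.alphas[-1]:g})")
for label in np.unique(spectrum.cluster_labels):
    members = spectrum.alphas[spectrum.cluster_labels == label]
    medoid = [a for a in spectrum.medoid_alphas if members.min() <= a <= members.max()]
    print(f"  cluster {label}: alpha in [{members.min():g}, {members.max():g}] "
          f"({len(members)} values), medoid alpha = {medoid[0]:g}")
print("medoid alphas returned to the user:",
      ", ".join(f"{a:g}" for a in spectrum.medoid_alphas))
print("-> each cluster is a regime where the contrastive subspace barely")
print("   changes; one representative alpha per regime is enough to inspect.")
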