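"""Separate sparse glyphs superimposed on dominant texture backgrounds.

Target images are smooth random textures with either a ring or a bar
glyph added at random contrast; background images are textures from the
same process with no glyphs.  The texture variance dominates the top
principal components, so PCA cannot separate the glyph classes; a
contrastive medoid view can, and its first component concentrates its
weight on the glyph pixels.
"""

import numpy as np
from sklearn.decomposition import PCA

from cpca import auto_cpca
from cpca.synthetic import kmeans_accuracy, make_glyph_scenario

scenario = make_glyph_scenario(seed=0)
results = auto_cpca(scenario.target, scenario.background, k=2, n_medoids=4)

accuracies = [kmeans_accuracy(e, scenario.labels) for _, e in results]
best = int(np.argmax(accuracies))
model = results[best][0]
union = scenario.ring_mask | scenario.bar_mask
w = model.components[:, 0]
mass = (w[union] ** 2).sum() / (w ** 2).sum()

pca_acc = kmeans_accuracy(
    PCA(n_components=2).fit_transform(scenario.target.values), scenario.labels
)

print(f"best medoid view: alpha={model.alpha:g}")
print(f"  2-means accuracy vs glyph labels: {accuracies[best]:.3f}")
print(f"  PCA (k=2) accuracy:               {pca_acc:.3f}")
print(f"  share of cPC1 squared weight on glyph pixels: {mass:.2f} "
      f"(glyphs cover {union.mean():.2f} of the image)")
print("-> cPCA separates ring from bar images and its first component")
print("   loads on the sparse glyph pixels, not the texture.")
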