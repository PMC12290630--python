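"""Binary and continuous similarity between group-level statistical maps.

Builds two correlated pseudo-group maps, thresholds them, and compares the
Jaccard / Dice overlap of the suprathreshold sets with the Spearman rank
correlation of the unthresholded values.
"""

import numpy as np

from relimap import image_similarity, pairwise_similarity

rng = np.random.default_rng(3)
shared = rng.normal(size=(10, 10, 10))
map_a = shared + 0.5 * rng.normal(size=shared.shape)
map_b = shared + 0.5 * rng.normal(size=shared.shape)

for metric in ("jaccard", "dice"):
    res = image_similarity(map_a, map_b, threshold=1.0, metric=metric)
    print(f"{metric} at threshold 1.0: {res.coefficient:.3f}")
print(f"spearman (unthresholded): "
      f"{image_similarity(map_a, map_b, metric='spearman').coefficient:.3f}")
res0 = image_similarity(map_a, map_b, threshold=0.0, metric="jaccard")
print(f"jaccard at threshold 0 (every voxel selected): {res0.coefficient:.1f}")

table = pairwise_similarity([map_a, map_b, shared], metric="spearman",
                            labels=["groupA", "groupB", "truth"])
print(table.to_string(index=False))

# Dice is always 2J/(1+J) of the Jaccard J; the Spearman value is higher than
# the overlap coefficients because it uses all voxels, not just the binarized
# suprathreshold sets. Threshold 0 selects everything, so overlap is 1 by
# construction.
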