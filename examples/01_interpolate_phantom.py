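"""Recover a dense segmentation from sparse slice annotations.

Builds a small two-sphere phantom with known dense ground truth, keeps
every 8th z-plane as the "manual" annotation, interpolates it through the
volume with intensity-weighted random walks, and scores the result
against the truth.  A Dice near 1 means the walks reconstructed the
unannotated 7/8 of the object from image intensities alone.
"""

import voxwalk as vw

img, dense = vw.two_object_phantom(contrast=60, noise_sd=8, rng_seed=11,
                                   shape=(48, 32, 32))
sparse = vw.sparsify_labels(dense, every_k=8)
n_annotated = len([p for p in range(48) if sparse.data[p].any()])
print(f"phantom {img.shape}, {len(dense.label_ids)} objects, "
      f"{n_annotated} annotated z-planes")

cfg = vw.WalkConfig(norw=4, sorw=800, rng_seed=21)
result = vw.interpolate(img, sparse, cfg=cfg)

score = vw.dice(result["labels"], dense)
print(f"seeds launched: {len(result['seeds'])}")
print(f"Dice vs dense ground truth: {score:.4f}")
print("(1.0 = perfect overlap of all labels; >0.95 = high-quality recovery)")
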