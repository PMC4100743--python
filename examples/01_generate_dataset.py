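"""Generate a seeded synthetic disguised-face dataset and inspect it.

Each subject is a procedural texture identity; disguised images overlay
dark or high-texture accessories on grid-aligned footprints, and every
patch carries a ground-truth biometric/non-biometric annotation
(non-biometric = more than half covered).
"""

import numpy as np

from patchverify import synthgen

spec = synthgen.SyntheticSpec(
    n_subjects=10, train_subjects=5,
    train_total_images=None, test_total_images=None, seed=42,
)
ds = synthgen.generate_dataset(spec)
m = ds.manifest()

print(f"images: {len(m)} ({(m.split == 'train').sum()} train / "
      f"{(m.split == 'test').sum()} test), subjects: {m.subject_id.nunique()}")
print(f"neutral images: {m.is_neutral.sum()}, disguised: {(~m.is_neutral).sum()}")

n_non_bio = sum(int(np.sum(im.annotation == "non_biometric")) for im in ds.images)
n_total = len(ds.images) * spec.grid.n_patches
print(f"patches: {n_total}, non-biometric: {n_non_bio} "
      f"({100 * n_non_bio / n_total:.1f}% — the occluded fraction the "
      f"classifier must detect)")

im = next(i for i in ds.images if not i.face.is_neutral)
print(f"\nexample disguised image {im.image_id} wears {im.accessories};")
print("its annotation grid (rows: forehead, eyes, nose, lips, chin):")
for row in im.annotation:
    print("  " + " ".join("X" if v == "non_biometric" else "." for v in row))
print("X = non-biometric (accessory-covered) patch, . = usable biometric patch")
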