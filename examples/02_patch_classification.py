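"""Train the biometric/non-biometric patch classifier and read its flags.

Each 26x30 patch is described by a 512-dim concatenation of its 256-bin
intensity histogram and 256-bin LBP histogram (both L1-normalized, then
min-max scaled over the training set). An RBF-SVM scores patches; the
threshold sits at the 95%-biometric-recall operating point so that few
genuine face patches are lost to the matcher.
"""

import numpy as np

from patchverify import patch_classifier, pipeline, synthgen

spec = synthgen.SyntheticSpec(
    n_subjects=14, train_subjects=7,
    train_total_images=None, test_total_images=None, seed=7,
)
ds = synthgen.generate_dataset(spec)
grid = ds.spec.grid

train_table = pipeline.extract_descriptors(ds.split_images("train"), grid)
test_table = pipeline.extract_descriptors(ds.split_images("test"), grid)
print(f"train patches: {train_table.X.shape[0]}, test patches: {test_table.X.shape[0]}")

model = pipeline.train_patch_classifier(
    train_table, seed=0,
    param_grid=patch_classifier.small_param_grid(), subsample=800,
)
print(f"grid-search CV accuracy: {model.cv_accuracy:.4f}, "
      f"best params: {model.best_params}")
print(f"threshold tau at 95% biometric recall: {model.tau:.3f}")

scores = patch_classifier.score_patches(model, test_table.X)
pred = np.where(scores < model.tau, "biometric", "non_biometric")
recovery = float(np.mean(pred == test_table.labels))
print(f"held-out flag recovery: {100 * recovery:.2f}% of patch labels "
      f"match the ground-truth annotations")

im = next(i for i in ds.split_images("test") if not i.face.is_neutral)
flags = patch_classifier.flag_matrix(model, im.face, grid)
agree = float(np.mean(flags == im.annotation))
print(f"\npredicted flag matrix for {im.image_id} "
      f"({100 * agree:.0f}% agreement with annotation):")
for row in flags:
    print("  " + " ".join("X" if v == "non_biometric" else "." for v in row))
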