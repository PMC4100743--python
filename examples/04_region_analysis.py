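"""Disguised-region combination analysis of verification errors.

The 5x5 grid maps to four facial regions (forehead = row 0, eyes = row
1, nose = row 2, lips/chin = rows 3-4); a region counts as disguised
when more than half its patches are non-biometric, giving 16 possible
region combinations per pair (union over the two images). The table
reports the misclassified fraction per combination.
"""

import numpy as np

from patchverify import evaluation, matcher, pipeline, synthgen

spec = synthgen.SyntheticSpec(
    n_subjects=14, train_subjects=7,
    train_total_images=None, test_total_images=None, seed=7,
)
ds = synthgen.generate_dataset(spec)
grid = ds.spec.grid
test_images = ds.split_images("test")
by_id = {im.image_id: im for im in test_images}
gallery, probe = synthgen.gallery_probe_split(ds, seed=0)

# verify every pair with ground-truth masks at a fixed distance threshold
flags = pipeline.ground_truth_flags(test_images, grid)
from patchverify.descriptors import face_lbp_histograms
hists = {im.image_id: face_lbp_histograms(im.face, grid) for im in test_images}

res = pipeline.verification_run(ds, mask_mode="ground_truth", trial_seed=0)
theta = float(np.quantile(res.impostor[np.isfinite(res.impostor)], 0.01))
print(f"decision threshold theta at 1% FAR: {theta:.4f}\n")

combos, correct = [], []
for pid in probe:
    for gid in gallery:
        mask = matcher.pair_mask(flags[gid], flags[pid])
        s = matcher.masked_distance_hists(hists[gid], hists[pid], mask)
        accept = matcher.verify(s, theta)
        genuine = by_id[gid].subject_id == by_id[pid].subject_id
        combos.append(
            evaluation.region_labels(by_id[gid].annotation)
            | evaluation.region_labels(by_id[pid].annotation)
        )
        correct.append(accept == genuine)

table = evaluation.combo_error_table(combos, correct)
print(table.to_string(index=False))
print("\nerror_fraction = share of pairs with that disguise combination that")
print("the verifier got wrong (false reject or false accept) at this theta.")
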