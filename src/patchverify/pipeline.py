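"""End-to-end experiment orchestration.

Ties the stages together: descriptor extraction over a dataset split,
patch-classifier training, flag prediction, masked verification, and the
three evaluation arms that probe the masking hypothesis — matching with
predicted flags, with ground-truth annotation flags, and with all-true
masks (the plain patch-wise LBP baseline).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import evaluation, matcher, patch_classifier
from .descriptors import face_descriptors, face_lbp_histograms
from .faceio import PatchGrid
from .patch_classifier import PatchClassifierModel
from .synthgen import SyntheticDataset, SyntheticImage, gallery_probe_split

__all__ = [
    "DescriptorTable",
    "VerificationResult",
    "extract_descriptors",
    "train_patch_classifier",
    "predicted_flags",
    "ground_truth_flags",
    "verification_run",
    "descriptor_block",
]

MASK_MODES = ("predicted", "ground_truth", "all")


@dataclasses.dataclass
class DescriptorTable:
    """Patch descriptors of one dataset split, row-major per image.

    ``X`` is (n_images * m * n, 512); ``labels`` holds the ground-truth
    patch annotations aligned with rows; ``image_ids`` the owning image.
    """

    X: np.ndarray
    labels: np.ndarray
    image_ids: np.ndarray


def extract_descriptors(
    images: list[SyntheticImage], grid: PatchGrid
) -> DescriptorTable:
    X, labels, ids = [], [], []
    for im in images:
        X.append(face_descriptors(im.face, grid))
        labels.append(im.annotation.ravel())
        ids.extend([im.image_id] * grid.n_patches)
    return DescriptorTable(
        X=np.vstack(X), labels=np.concatenate(labels), image_ids=np.asarray(ids)
    )


def descriptor_block(X: np.ndarray, block: str) -> np.ndarray:
    """Select the "intensity" (0-255), "lbp" (256-511), or "ite" columns."""
    if block == "ite":
        return X
    if block == "intensity":
        return X[:, :256]
    if block == "lbp":
        return X[:, 256:]
    raise ValueError(f"unknown descriptor block {block!r}")


def train_patch_classifier(
    train_table: DescriptorTable,
    seed: int = 0,
    *,
    block: str = "ite",
    param_grid: dict | None = None,
    subsample: int | None = None,
    operating_point: str = "biometric_recall",
    recall: float = 0.95,
) -> PatchClassifierModel:
    """Train the SVM on a split's descriptors and set its threshold.

    ``subsample`` caps the number of training patches (seeded,
    stratified by keeping the draw order random) to bound grid-search
    cost on large splits; the threshold is then chosen on *all* training
    scores at the requested operating point.
    """
    X = descriptor_block(train_table.X, block)
    y = train_table.labels
    if subsample is not None and subsample < X.shape[0]:
        rng = np.random.default_rng(seed)
        idx = rng.permutation(X.shape[0])[:subsample]
        Xs, ys = X[idx], y[idx]
    else:
        Xs, ys = X, y
    model = patch_classifier.train_classifier(
        Xs, ys, seed=seed, param_grid=param_grid
    )
    scores = patch_classifier.score_patches(model, X)
    model.tau = patch_classifier.choose_threshold(
        scores, y, operating_point, recall=recall
    )
    return model


def predicted_flags(
    model: PatchClassifierModel,
    images: list[SyntheticImage],
    grid: PatchGrid,
) -> dict[str, np.ndarray]:
    """image_id -> (m, n) boolean flag matrix (true = biometric)."""
    out = {}
    for im in images:
        flags = patch_classifier.flag_matrix(model, im.face, grid)
        out[im.image_id] = flags == patch_classifier.BIOMETRIC
    return out


def ground_truth_flags(
    images: list[SyntheticImage], grid: PatchGrid
) -> dict[str, np.ndarray]:
    return {
        im.image_id: im.annotation == patch_classifier.BIOMETRIC for im in images
    }


@dataclasses.dataclass
class VerificationResult:
    genuine: np.ndarray
    impostor: np.ndarray
    curve: evaluation.ROCCurve
    n_zero_mask_pairs: int

    def gar_at_far(self, far: float) -> float:
        return evaluation.gar_at_far(self.curve, far)


def verification_run(
    dataset: SyntheticDataset,
    *,
    mask_mode: str = "ground_truth",
    model: PatchClassifierModel | None = None,
    trial_seed: int = 0,
    aggregate: str = "mean",
) -> VerificationResult:
    """One gallery/probe verification trial on the test split.

    ``mask_mode``: "predicted" uses SVM flag matrices (requires
    ``model``), "ground_truth" the annotation flags, "all" the all-true
    mask (plain LBP baseline). Returns genuine/impostor distance arrays
    and the ROC.
    """
    if mask_mode not in MASK_MODES:
        raise ValueError(f"mask_mode must be one of {MASK_MODES}")
    grid = dataset.spec.grid
    test_images = dataset.split_images("test")
    by_id = {im.image_id: im for im in test_images}
    gallery_ids, probe_ids = gallery_probe_split(dataset, seed=trial_seed)

    if mask_mode == "predicted":
        if model is None:
            raise ValueError("mask_mode='predicted' requires a trained model")
        flags = predicted_flags(model, test_images, grid)
    elif mask_mode == "ground_truth":
        flags = ground_truth_flags(test_images, grid)
    else:
        all_true = np.ones((grid.m, grid.n), dtype=bool)
        flags = {im.image_id: all_true for im in test_images}

    hists = {
        im.image_id: face_lbp_histograms(im.face, grid) for im in test_images
    }
    genuine, impostor = [], []
    n_zero = 0
    for pid in probe_ids:
        for gid in gallery_ids:
            mask = matcher.pair_mask(flags[gid], flags[pid])
            score = matcher.masked_distance_hists(
                hists[gid], hists[pid], mask, aggregate=aggregate
            )
            if score.used_patches == 0:
                n_zero += 1
            same = by_id[gid].subject_id == by_id[pid].subject_id
            (genuine if same else impostor).append(score.distance)
    genuine = np.asarray(genuine)
    impostor = np.asarray(impostor)
    return VerificationResult(
        genuine=genuine,
        impostor=impostor,
        curve=evaluation.roc(genuine, impostor),
        n_zero_mask_pairs=n_zero,
    )
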