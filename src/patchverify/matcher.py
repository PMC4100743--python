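"""Pair masking and masked LBP chi-square face matching.

A gallery-probe pair only compares patches that *both* images agree are
biometric: the pair mask is the logical AND of the two flag matrices.
The match distance is the chi-square distance between per-patch LBP
histograms, averaged over masked-in patches (mean keeps scores
comparable across pairs that use different numbers of patches; a sum
mode is available). A pair with no usable patch gets distance +inf and
is rejected at every threshold — the analogue of a failure to enroll.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .descriptors import CHI2_EPS, face_lbp_histograms
from .faceio import NormalizedFace, PatchGrid
from .patch_classifier import BIOMETRIC

__all__ = ["MatchScore", "pair_mask", "masked_distance", "masked_distance_hists", "verify"]


@dataclasses.dataclass(frozen=True)
class MatchScore:
    distance: float
    used_patches: int

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValueError("distance must be non-negative")
        if np.isfinite(self.distance) != (self.used_patches > 0):
            raise ValueError("distance is finite iff some patch was used")


def _as_biometric_bool(flags: np.ndarray) -> np.ndarray:
    flags = np.asarray(flags)
    if flags.dtype == bool:
        return flags
    return flags == BIOMETRIC


def pair_mask(flags_gallery: np.ndarray, flags_probe: np.ndarray) -> np.ndarray:
    """Boolean (m, n) mask: true where both faces' patches are biometric.

    Accepts label-string flag matrices or boolean ones (true = biometric).
    """
    fg = _as_biometric_bool(flags_gallery)
    fp = _as_biometric_bool(flags_probe)
    if fg.shape != fp.shape:
        raise ValueError(f"flag matrix shapes differ: {fg.shape} vs {fp.shape}")
    return fg & fp


def masked_distance_hists(
    hists_gallery: np.ndarray,
    hists_probe: np.ndarray,
    mask: np.ndarray,
    *,
    aggregate: str = "mean",
) -> MatchScore:
    """Masked chi-square distance from precomputed per-patch LBP histograms.

    ``hists_*`` are (n_patches, 256) row-major; ``mask`` is (m, n) or flat.
    """
    hg = np.asarray(hists_gallery, dtype=float)
    hp = np.asarray(hists_probe, dtype=float)
    flat = np.asarray(mask).ravel().astype(bool)
    if hg.shape != hp.shape or hg.shape[0] != flat.size:
        raise ValueError("histogram/mask geometry mismatch")
    used = int(flat.sum())
    if used == 0:
        return MatchScore(float("inf"), 0)
    d = ((hg[flat] - hp[flat]) ** 2 / (hg[flat] + hp[flat] + CHI2_EPS)).sum(axis=1)
    if aggregate == "mean":
        return MatchScore(float(d.mean()), used)
    if aggregate == "sum":
        return MatchScore(float(d.sum()), used)
    raise ValueError(f"unknown aggregate mode: {aggregate!r}")


def masked_distance(
    gallery: NormalizedFace,
    probe: NormalizedFace,
    mask: np.ndarray,
    grid: PatchGrid,
    *,
    aggregate: str = "mean",
) -> MatchScore:
    """Masked chi-square distance between two canonical faces."""
    if gallery.pixels.shape != probe.pixels.shape:
        raise ValueError("gallery/probe geometry mismatch")
    mask = np.asarray(mask)
    if mask.shape != (grid.m, grid.n):
        raise ValueError(f"mask shape {mask.shape} does not match grid {(grid.m, grid.n)}")
    return masked_distance_hists(
        face_lbp_histograms(gallery, grid),
        face_lbp_histograms(probe, grid),
        mask,
        aggregate=aggregate,
    )


def verify(score: MatchScore | float, threshold: float) -> bool:
    """Accept iff the distance is finite and <= threshold (inclusive)."""
    d = score.distance if isinstance(score, MatchScore) else float(score)
    return bool(np.isfinite(d) and d <= threshold)
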