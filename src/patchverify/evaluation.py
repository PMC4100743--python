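"""Verification metrics and disguise-region error analysis.

Rates follow the standard verification bookkeeping: with GA/FA/GR/FR the
counts of genuinely accepted, falsely accepted, genuinely rejected and
falsely rejected pairs, FAR = FA/(FA+GR), GAR = GA/(GA+FR) and accuracy =
(GA+GR)/total, all reported as percentages. ROC curves sweep the decision
threshold over every distinct finite distance (a pair is accepted when
its distance <= threshold; infinite distances count as rejections at
every threshold and their number is reported separately).

The region analysis maps the 5x5 patch grid onto four facial regions —
forehead (row 0), eyes (row 1), nose (row 2) and lips/chin (rows 3-4) —
and calls a region disguised when strictly more than half of its patches
are non-biometric, giving 16 possible region combinations.
"""

from __future__ import annotations

import dataclasses
from itertools import combinations

import numpy as np
import pandas as pd

from .patch_classifier import BIOMETRIC

__all__ = [
    "ResponseCounts",
    "ROCCurve",
    "REGIONS",
    "rates",
    "roc",
    "gar_at_far",
    "eer",
    "region_labels",
    "all_region_combos",
    "combo_error_table",
    "summary_table",
]

REGIONS = ("forehead", "eyes", "nose", "lips_chin")

#: Grid rows belonging to each region (5x5 grid only).
_REGION_ROWS = {"forehead": [0], "eyes": [1], "nose": [2], "lips_chin": [3, 4]}


@dataclasses.dataclass(frozen=True)
class ResponseCounts:
    """Genuine-accept / false-accept / genuine-reject / false-reject counts."""

    GA: int
    FA: int
    GR: int
    FR: int

    def __post_init__(self) -> None:
        if min(self.GA, self.FA, self.GR, self.FR) < 0:
            raise ValueError("counts must be non-negative")


def rates(c: ResponseCounts) -> tuple[float, float, float]:
    """(FAR%, GAR%, accuracy%) from response counts."""
    genuine = c.GA + c.FR
    impostor = c.FA + c.GR
    if genuine == 0:
        raise ZeroDivisionError("no genuine pairs: GAR undefined")
    if impostor == 0:
        raise ZeroDivisionError("no impostor pairs: FAR undefined")
    far = 100.0 * c.FA / impostor
    gar = 100.0 * c.GA / genuine
    acc = 100.0 * (c.GA + c.GR) / (genuine + impostor)
    return far, gar, acc


@dataclasses.dataclass
class ROCCurve:
    """Operating points (threshold, FAR, GAR), fractions in [0, 1].

    Ordered by increasing threshold; FAR and GAR are non-decreasing.
    ``n_genuine_inf``/``n_impostor_inf`` count pairs with infinite
    distance, which are rejected at every threshold but kept in the
    denominators.
    """

    thresholds: np.ndarray
    far: np.ndarray
    gar: np.ndarray
    n_genuine: int
    n_impostor: int
    n_genuine_inf: int = 0
    n_impostor_inf: int = 0


def roc(genuine: np.ndarray, impostor: np.ndarray) -> ROCCurve:
    """ROC from genuine and impostor distances (smaller = more similar)."""
    genuine = np.asarray(genuine, dtype=float)
    impostor = np.asarray(impostor, dtype=float)
    if genuine.size == 0 or impostor.size == 0:
        raise ValueError("need at least one distance per class")
    g_fin = genuine[np.isfinite(genuine)]
    i_fin = impostor[np.isfinite(impostor)]
    thresholds = np.unique(np.concatenate([g_fin, i_fin]))
    if thresholds.size == 0:
        raise ValueError("all distances are infinite; ROC undefined")
    # accept iff distance <= threshold
    gar = np.searchsorted(np.sort(g_fin), thresholds, side="right") / genuine.size
    far = np.searchsorted(np.sort(i_fin), thresholds, side="right") / impostor.size
    return ROCCurve(
        thresholds=thresholds,
        far=far,
        gar=gar,
        n_genuine=genuine.size,
        n_impostor=impostor.size,
        n_genuine_inf=int(genuine.size - g_fin.size),
        n_impostor_inf=int(impostor.size - i_fin.size),
    )


def gar_at_far(curve: ROCCurve, far: float) -> float:
    """GAR (fraction) at the requested FAR, linearly interpolated.

    Below the smallest achieved FAR the most conservative operating point
    is extended (GAR at threshold -inf is 0 at FAR 0).
    """
    if not 0.0 <= far <= 1.0:
        raise ValueError("FAR must be a fraction in [0, 1]")
    xs = np.concatenate([[0.0], curve.far])
    ys = np.concatenate([[0.0], curve.gar])
    return float(np.interp(far, xs, ys))


def eer(curve: ROCCurve) -> float:
    """Equal error rate: rate where FAR and FRR (=1-GAR) coincide.

    Returns the midpoint (FAR + FRR)/2 at the operating point minimizing
    |FAR - FRR|.
    """
    frr = 1.0 - curve.gar
    i = int(np.argmin(np.abs(curve.far - frr)))
    return float((curve.far[i] + frr[i]) / 2.0)


def region_labels(flags: np.ndarray) -> frozenset[str]:
    """Disguised-region combination of a 5x5 flag/annotation grid.

    Accepts a label-string matrix or boolean matrix (true = biometric). A
    region is disguised iff strictly more than half of its patches are
    non-biometric.
    """
    flags = np.asarray(flags)
    if flags.shape != (5, 5):
        raise ValueError(f"region analysis requires a 5x5 grid, got {flags.shape}")
    non_bio = ~(flags == BIOMETRIC) if flags.dtype != bool else ~flags
    disguised = set()
    for region, rows in _REGION_ROWS.items():
        patches = non_bio[rows, :]
        if patches.sum() * 2 > patches.size:
            disguised.add(region)
    return frozenset(disguised)


def all_region_combos() -> list[frozenset[str]]:
    """All 16 subsets of the four facial regions, by size then name."""
    combos = []
    for k in range(len(REGIONS) + 1):
        for subset in combinations(REGIONS, k):
            combos.append(frozenset(subset))
    return combos


def combo_name(combo: frozenset[str]) -> str:
    if not combo:
        return "none"
    return "+".join(r for r in REGIONS if r in combo)


def combo_error_table(
    pair_combos: list[frozenset[str]],
    pair_correct: list[bool],
) -> pd.DataFrame:
    """Misclassified fraction per disguised-region combination.

    Rows: one per combination that occurs, with pair count, error count
    and error fraction; combinations with no pairs are absent.
    """
    if len(pair_combos) != len(pair_correct):
        raise ValueError("pair_combos and pair_correct lengths differ")
    rows = []
    for combo in all_region_combos():
        idx = [i for i, c in enumerate(pair_combos) if c == combo]
        if not idx:
            continue
        errors = sum(1 for i in idx if not pair_correct[i])
        rows.append({
            "combination": combo_name(combo),
            "n_pairs": len(idx),
            "n_errors": errors,
            "error_fraction": errors / len(idx),
        })
    return pd.DataFrame(rows)


def summary_table(curve: ROCCurve, far_points: tuple[float, ...] = (0.001, 0.01, 0.10)) -> pd.DataFrame:
    """GAR (%) at the standard reporting FAR points, plus EER (%)."""
    rows = [
        {"metric": f"GAR@FAR={100 * f:g}%", "value_pct": 100.0 * gar_at_far(curve, f)}
        for f in far_points
    ]
    rows.append({"metric": "EER", "value_pct": 100.0 * eer(curve)})
    return pd.DataFrame(rows)
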