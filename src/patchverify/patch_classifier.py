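"""Biometric vs non-biometric patch classification.

An RBF-kernel SVM is trained on joint intensity+texture patch descriptors
(min-max normalized to [0,1]); hyperparameters are chosen by seeded grid
search with 5-fold cross-validation. Scores are signed SVM decision
values with the non-biometric class positive, so the decision rule reads:
score < tau -> biometric, score >= tau -> non-biometric. The operating
threshold tau defaults to the 95%-biometric-recall point, which keeps
most genuine face patches available to the matcher; the equal-error-rate
point is also supported.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import joblib
import numpy as np
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from .descriptors import MinMaxModel, face_descriptors, minmax_apply, minmax_fit
from .faceio import NormalizedFace, PatchGrid

__all__ = [
    "BIOMETRIC",
    "NON_BIOMETRIC",
    "PatchClassifierModel",
    "default_param_grid",
    "small_param_grid",
    "train_classifier",
    "score_patch",
    "classify_patch",
    "flag_matrix",
    "choose_threshold",
    "save_model",
    "load_model",
]

BIOMETRIC = "biometric"
NON_BIOMETRIC = "non_biometric"


def default_param_grid() -> dict[str, list[float]]:
    """C in 2^-3..2^15 and gamma in 2^-15..2^3, both stepping x4."""
    return {
        "C": [2.0**e for e in range(-3, 16, 2)],
        "gamma": [2.0**e for e in range(-15, 4, 2)],
    }


def small_param_grid() -> dict[str, list[float]]:
    """Coarse 3x3 subgrid of the default grid, for quick runs."""
    return {
        "C": [2.0**e for e in (-1, 5, 11)],
        "gamma": [2.0**e for e in (-9, -3, 1)],
    }


@dataclasses.dataclass
class PatchClassifierModel:
    svc: SVC
    minmax: MinMaxModel
    tau: float = 0.0
    cv_accuracy: float = float("nan")
    best_params: dict | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.tau):
            raise ValueError("tau must be finite")


def train_classifier(
    descriptors: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    *,
    param_grid: dict | None = None,
    cv_folds: int = 5,
    balance_classes: bool = False,
    tau: float = 0.0,
) -> PatchClassifierModel:
    """Fit the RBF-SVM patch classifier with seeded grid search.

    ``labels`` are strings from {"biometric", "non_biometric"}. Raw
    descriptors are min-max normalized internally; the learned ranges are
    stored on the model and reapplied at scoring time. ``balance_classes``
    weights the misclassification cost by inverse class frequency.
    """
    X = np.asarray(descriptors, dtype=float)
    y = np.asarray(labels)
    classes = set(np.unique(y))
    if classes != {BIOMETRIC, NON_BIOMETRIC}:
        raise ValueError(
            f"need both patch classes in training labels, got {sorted(classes)}"
        )
    mm = minmax_fit(X)
    Xn = minmax_apply(mm, X)

    svc = SVC(
        kernel="rbf",
        class_weight="balanced" if balance_classes else None,
    )
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    search = GridSearchCV(
        svc,
        param_grid or default_param_grid(),
        scoring="accuracy",
        cv=cv,
        n_jobs=1,
        refit=True,
    )
    search.fit(Xn, y)
    return PatchClassifierModel(
        svc=search.best_estimator_,
        minmax=mm,
        tau=tau,
        cv_accuracy=float(search.best_score_),
        best_params=dict(search.best_params_),
    )


def _scores(model: PatchClassifierModel, descriptors: np.ndarray) -> np.ndarray:
    Xn = minmax_apply(model.minmax, np.atleast_2d(np.asarray(descriptors, dtype=float)))
    raw = model.svc.decision_function(Xn)
    # decision_function is positive towards classes_[1]; fix polarity so
    # larger always means more non-biometric.
    if list(model.svc.classes_) == [BIOMETRIC, NON_BIOMETRIC]:
        return raw
    return -raw


def score_patch(model: PatchClassifierModel, descriptor: np.ndarray) -> float:
    """Signed SVM score for one descriptor; larger = more non-biometric."""
    return float(_scores(model, descriptor)[0])


def score_patches(model: PatchClassifierModel, descriptors: np.ndarray) -> np.ndarray:
    """Vectorized :func:`score_patch` over rows of a descriptor matrix."""
    return _scores(model, descriptors)


def classify_patch(score: float, tau: float) -> str:
    """biometric iff score < tau; ties go to non-biometric."""
    return BIOMETRIC if score < tau else NON_BIOMETRIC


def flag_matrix(
    model: PatchClassifierModel,
    face: NormalizedFace,
    grid: PatchGrid,
    *,
    tau: float | None = None,
) -> np.ndarray:
    """Per-patch labels for one face as an (m, n) array of label strings."""
    t = model.tau if tau is None else tau
    scores = _scores(model, face_descriptors(face, grid))
    labels = np.array([classify_patch(s, t) for s in scores])
    return labels.reshape(grid.m, grid.n)


def choose_threshold(
    scores: np.ndarray,
    labels: np.ndarray,
    operating_point: str = "biometric_recall",
    *,
    recall: float = 0.95,
) -> float:
    """Pick tau from validation scores at a named operating point.

    "biometric_recall": smallest tau with at least ``recall`` of biometric
    patches scored below it.  "eer": tau minimizing |FPR - FNR| where the
    non-biometric class is positive; ties break towards the smallest tau.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    bio = np.sort(scores[labels == BIOMETRIC])
    non = np.sort(scores[labels == NON_BIOMETRIC])
    if bio.size == 0 or non.size == 0:
        raise ValueError("need validation scores from both classes")

    # candidate thresholds: just above every score, plus extremes
    eps = 1e-9
    candidates = np.unique(np.concatenate([
        [scores.min() - 1.0], scores + eps,
    ]))
    if operating_point == "biometric_recall":
        if not 0.0 <= recall <= 1.0:
            raise ValueError("recall must be in [0, 1]")
        for t in candidates:
            if np.mean(bio < t) >= recall:
                return float(t)
        raise ValueError(f"biometric recall {recall} unattainable")
    if operating_point == "eer":
        best_t, best_gap = None, np.inf
        for t in candidates:
            fnr = np.mean(non < t)      # non-biometric wrongly accepted as biometric
            fpr = np.mean(bio >= t)     # biometric wrongly flagged
            gap = abs(fpr - fnr)
            if gap < best_gap - 1e-12:
                best_gap, best_t = gap, t
        return float(best_t)
    raise ValueError(f"unknown operating point: {operating_point!r}")


def save_model(model: PatchClassifierModel, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    joblib.dump(model, path)


def load_model(path: str | Path) -> PatchClassifierModel:
    model = joblib.load(path)
    if not isinstance(model, PatchClassifierModel):
        raise TypeError(f"{path} does not contain a PatchClassifierModel")
    return model
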