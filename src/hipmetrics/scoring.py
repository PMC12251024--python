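"""Weighted angle-scoring system for DDH diagnosis, with CV grid-search calibration.

Each of the three radiographic angles is categorized into one of three
classes against standard clinical criteria:

====== =========== ============ ==========
angle   normal      borderline   DDH
====== =========== ============ ==========
CE      > 25°       20°–25°      < 20°
Tönnis  < 10°       10°–13°      > 13°
Sharp   < 42°       42°–47°      > 47°
====== =========== ============ ==========

Boundary values fall in the closed borderline interval.  Each category maps
to an integer score (default: normal 0 everywhere; borderline 1 everywhere;
DDH scores 3 for CE and 2 for Tönnis and Sharp), the three scores are
summed, and the hip is diagnosed "DDH present" when the total reaches the
decision threshold (default 5).  The CE angle deliberately carries the
largest DDH weight: lateral femoral-head coverage is the most reliable
single index, and a positive diagnosis under the defaults is impossible
without at least a borderline CE.

``calibrate`` re-derives the score weights and threshold from data: an
exhaustive grid search over integer score assignments evaluated by
stratified k-fold cross-validated F1, selecting the candidate with maximal
mean F1, breaking ties by minimal across-fold variance, then smallest
threshold, then lexicographically smallest score vector.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .geometry import AngleMeasurements

__all__ = [
    "ANGLES",
    "CATEGORIES",
    "CategoryCriteria",
    "ScoringParams",
    "Diagnosis",
    "categorize",
    "categorize_measurements",
    "score_hip",
    "diagnose_from_angles",
    "f1_score",
    "CalibrationResult",
    "calibrate",
    "ensemble_measurements",
]

ANGLES = ("ce", "tonnis", "sharp")
CATEGORIES = ("normal", "borderline", "ddh")


@dataclass(frozen=True)
class CategoryCriteria:
    """Per-angle (low, high) category boundaries, in degrees.

    ``higher_is_better`` marks angles for which larger values are healthier
    (true only for CE): for those, normal is above ``high`` and DDH below
    ``low``; for the others the orientation is reversed.  Exact boundary
    values are borderline.
    """

    ce: tuple[float, float] = (20.0, 25.0)
    tonnis: tuple[float, float] = (10.0, 13.0)
    sharp: tuple[float, float] = (42.0, 47.0)
    higher_is_better: tuple[bool, bool, bool] = (True, False, False)

    def __post_init__(self) -> None:
        for name in ANGLES:
            low, high = getattr(self, name)
            if not low < high:
                raise ValueError(f"{name}: low boundary must be below high boundary")

    def bounds(self, which: str) -> tuple[float, float, bool]:
        if which not in ANGLES:
            raise ValueError(f"unknown angle {which!r}; expected one of {ANGLES}")
        low, high = getattr(self, which)
        return low, high, self.higher_is_better[ANGLES.index(which)]


@dataclass(frozen=True)
class ScoringParams:
    """Integer scores per angle and category, plus the diagnostic threshold.

    ``scores[angle] = (normal, borderline, ddh)``; monotone non-decreasing in
    severity.  The shipped defaults are the calibrated clinical table:
    CE (0, 1, 3), Tönnis (0, 1, 2), Sharp (0, 1, 2), threshold 5.
    """

    ce: tuple[int, int, int] = (0, 1, 3)
    tonnis: tuple[int, int, int] = (0, 1, 2)
    sharp: tuple[int, int, int] = (0, 1, 2)
    threshold: int = 5

    def __post_init__(self) -> None:
        for name in ANGLES:
            triple = getattr(self, name)
            if any(int(s) != s or s < 0 for s in triple):
                raise ValueError(f"{name}: scores must be non-negative integers")
            if not (triple[0] <= triple[1] <= triple[2]):
                raise ValueError(f"{name}: scores must be monotone in severity")
        if self.threshold < 0:
            raise ValueError("threshold must be non-negative")

    def score(self, which: str, category: str) -> int:
        return getattr(self, which)[CATEGORIES.index(category)]

    def max_total(self) -> int:
        return sum(getattr(self, a)[2] for a in ANGLES)


@dataclass(frozen=True)
class Diagnosis:
    """Explainable diagnosis for one hip: per-angle breakdown, total, decision."""

    total_score: int
    positive: bool
    breakdown: dict  # angle -> (category, score)
    threshold: int

    @property
    def label(self) -> str:
        return "DDH present" if self.positive else "DDH absent"


def categorize(angle_deg: float, which: str, criteria: CategoryCriteria | None = None) -> str:
    """Assign one angle value to normal / borderline / ddh."""
    criteria = criteria or CategoryCriteria()
    if not math.isfinite(angle_deg):
        raise ValueError(f"non-finite {which} angle")
    low, high, hib = criteria.bounds(which)
    if hib:
        if angle_deg > high:
            return "normal"
        if angle_deg >= low:
            return "borderline"
        return "ddh"
    if angle_deg < low:
        return "normal"
    if angle_deg <= high:
        return "borderline"
    return "ddh"


def categorize_measurements(
    m: AngleMeasurements, criteria: CategoryCriteria | None = None
) -> dict[str, str]:
    return {
        "ce": categorize(m.ce_deg, "ce", criteria),
        "tonnis": categorize(m.tonnis_deg, "tonnis", criteria),
        "sharp": categorize(m.sharp_deg, "sharp", criteria),
    }


def score_hip(categories: dict[str, str] | Sequence[str], params: ScoringParams | None = None) -> Diagnosis:
    """Sum the per-angle scores of a category triple and apply the threshold."""
    params = params or ScoringParams()
    if not isinstance(categories, dict):
        categories = dict(zip(ANGLES, categories))
    if set(categories) != set(ANGLES):
        raise ValueError(f"need categories for exactly {ANGLES}")
    breakdown = {a: (categories[a], params.score(a, categories[a])) for a in ANGLES}
    total = sum(s for _, s in breakdown.values())
    return Diagnosis(total, total >= params.threshold, breakdown, params.threshold)


def diagnose_from_angles(
    m: AngleMeasurements,
    criteria: CategoryCriteria | None = None,
    params: ScoringParams | None = None,
) -> Diagnosis:
    """Categorize all three angles of one hip, then score and threshold."""
    return score_hip(categorize_measurements(m, criteria), params)


def f1_score(predicted: Sequence[int], truth: Sequence[int]) -> float:
    """F1 = 2TP / (2TP + FP + FN) for binary labels; 0 when the denominator is 0."""
    pred = np.asarray(predicted, dtype=bool)
    true = np.asarray(truth, dtype=bool)
    if pred.shape != true.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {true.shape}")
    if pred.size == 0:
        raise ValueError("empty label vectors")
    tp = int(np.sum(pred & true))
    fp = int(np.sum(pred & ~true))
    fn = int(np.sum(~pred & true))
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def ensemble_measurements(per_model: Sequence[AngleMeasurements]) -> AngleMeasurements:
    """Arithmetic mean of each angle across models for the same hip."""
    if len(per_model) == 0:
        raise ValueError("empty measurement list")
    sides = {m.side for m in per_model}
    if len(sides) != 1:
        raise ValueError(f"mixed sides in ensemble: {sorted(sides)}")
    return AngleMeasurements(
        side=per_model[0].side,
        ce_deg=float(np.mean([m.ce_deg for m in per_model])),
        tonnis_deg=float(np.mean([m.tonnis_deg for m in per_model])),
        sharp_deg=float(np.mean([m.sharp_deg for m in per_model])),
    )


# ---------------------------------------------------------------------------
# Grid-search calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationResult:
    params: ScoringParams
    mean_f1: float
    var_f1: float
    #: one row per candidate: scores, threshold, per-fold F1, mean, variance
    table: pd.DataFrame
    #: candidates whose fold-wise F1 vector is identical to the winner's
    equivalent_candidates: list[ScoringParams] = field(default_factory=list)


def _category_codes(angles: np.ndarray, criteria: CategoryCriteria) -> np.ndarray:
    """Vectorized categorization: (n, 3) angles -> (n, 3) codes 0/1/2."""
    codes = np.empty(angles.shape, dtype=np.int64)
    for j, name in enumerate(ANGLES):
        low, high, hib = criteria.bounds(name)
        a = angles[:, j]
        if hib:
            codes[:, j] = np.where(a > high, 0, np.where(a >= low, 1, 2))
        else:
            codes[:, j] = np.where(a < low, 0, np.where(a <= high, 1, 2))
    return codes


def calibrate(
    angle_table: pd.DataFrame,
    *,
    criteria: CategoryCriteria | None = None,
    ddh_range: Sequence[int] = (1, 2, 3, 4),
    borderline_range: Sequence[int] = (1,),
    threshold_range: Sequence[int] = tuple(range(1, 13)),
    k: int = 10,
    seed: int = 0,
) -> CalibrationResult:
    """Grid-search the score weights and threshold by stratified k-fold CV F1.

    ``angle_table`` must have columns ``ce_deg, tonnis_deg, sharp_deg, label``
    (label 0/1).  Normal scores are fixed at 0; borderline scores default to
    the fixed value 1 but may be searched by passing a wider
    ``borderline_range``; DDH scores are searched per angle over
    ``ddh_range``.  Candidates violating score monotonicity
    (borderline > ddh) are excluded.

    For each candidate the F1 score is computed on each of ``k`` stratified
    validation folds; the winner maximizes mean F1, then minimizes across-
    fold variance, then threshold, then the lexicographic score vector.
    """
    criteria = criteria or CategoryCriteria()
    if k < 2:
        raise ValueError("k must be at least 2")
    required = {"ce_deg", "tonnis_deg", "sharp_deg", "label"}
    if not required.issubset(angle_table.columns):
        raise ValueError(f"angle table must have columns {sorted(required)}")
    labels = angle_table["label"].to_numpy(dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("calibration requires both positive and negative labels")

    angles = angle_table[["ce_deg", "tonnis_deg", "sharp_deg"]].to_numpy(dtype=float)
    codes = _category_codes(angles, criteria)

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = [val for _, val in skf.split(np.zeros(len(labels)), labels)]
    for i, val in enumerate(folds):
        if labels[val].sum() == 0:
            raise ValueError(
                f"fold {i} has no positive labels; reduce k or provide more positives"
            )

    onehot = np.eye(3, dtype=np.int64)[codes]  # (n, 3 angles, 3 cats)

    rows = []
    fold_vectors: dict[tuple, np.ndarray] = {}
    for b_ce, b_t, b_s in itertools.product(borderline_range, repeat=3):
        for d_ce, d_t, d_s in itertools.product(ddh_range, repeat=3):
            if d_ce < b_ce or d_t < b_t or d_s < b_s:
                continue
            score_mat = np.array(
                [[0, b_ce, d_ce], [0, b_t, d_t], [0, b_s, d_s]], dtype=np.int64
            )
            totals = np.einsum("nac,ac->n", onehot, score_mat)
            for thr in threshold_range:
                pred = totals >= thr
                f1s = np.array([f1_score(pred[val], labels[val]) for val in folds])
                key = ((b_ce, b_t, b_s), (d_ce, d_t, d_s), thr)
                fold_vectors[key] = f1s
                rows.append(
                    {
                        "borderline": (b_ce, b_t, b_s),
                        "ddh": (d_ce, d_t, d_s),
                        "threshold": thr,
                        "mean_f1": float(f1s.mean()),
                        "var_f1": float(f1s.var(ddof=0)),
                        "fold_f1": tuple(np.round(f1s, 12)),
                    }
                )
    table = pd.DataFrame(rows)
    best = table.sort_values(
        by=["mean_f1", "var_f1", "threshold", "borderline", "ddh"],
        ascending=[False, True, True, True, True],
        kind="mergesort",
    ).iloc[0]
    b, d = best["borderline"], best["ddh"]
    winner = ScoringParams(
        ce=(0, b[0], d[0]),
        tonnis=(0, b[1], d[1]),
        sharp=(0, b[2], d[2]),
        threshold=int(best["threshold"]),
    )
    win_vec = fold_vectors[(tuple(b), tuple(d), int(best["threshold"]))]
    equivalents = [
        ScoringParams(
            ce=(0, kb[0], kd[0]), tonnis=(0, kb[1], kd[1]), sharp=(0, kb[2], kd[2]), threshold=kt
        )
        for (kb, kd, kt), vec in fold_vectors.items()
        if np.allclose(vec, win_vec) and (kb, kd, kt) != (tuple(b), tuple(d), int(best["threshold"]))
    ]
    return CalibrationResult(
        params=winner,
        mean_f1=float(best["mean_f1"]),
        var_f1=float(best["var_f1"]),
        table=table,
        equivalent_candidates=equivalents,
    )
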