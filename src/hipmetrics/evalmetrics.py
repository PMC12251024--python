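"""Evaluation statistics: OKS detection metrics and agreement analyses.

Keypoint detections are scored with object keypoint similarity (OKS): for
keypoint ``i`` displaced by Euclidean distance ``d_i`` from ground truth,

    OKS_i = exp(-d_i^2 / (2 s^2 k_i^2)),

where ``s^2`` is the ground-truth bounding-box area (object scale) and
``k_i`` a per-keypoint falloff constant reflecting how reproducibly human
experts can place that landmark.  A keypoint is a true positive at a
threshold when its similarity strictly exceeds it; precision and recall are
averaged over thresholds 0.50 to 0.95 in steps of 0.05 to give mAP and mAR.

Agreement between measurement methods uses the intraclass correlation
coefficient (two-way random effects, absolute agreement, single measurement
— ICC(2,1) — with F-distribution 95% confidence bounds), Bland-Altman bias
and 95% limits of agreement, and the Mann-Whitney U test for distributional
comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .detector import DetectorConfig, TrainConfig, train_detector
from .geometry import KEYPOINT_ORDER, PelvisAnnotation
from .phantom import RaterModel

__all__ = [
    "OKS_THRESHOLDS",
    "OKSConfig",
    "DetectionPR",
    "AgreementReport",
    "oks",
    "pr_at_threshold",
    "map_mar",
    "icc",
    "bland_altman",
    "mann_whitney",
    "sensitivity_table",
]

#: The fixed OKS threshold grid: 0.50, 0.55, ..., 0.95.
OKS_THRESHOLDS = tuple(np.round(np.linspace(0.50, 0.95, 10), 2))


@dataclass(frozen=True)
class OKSConfig:
    """Per-keypoint-label OKS falloff constants (unitless).

    ``per_label`` maps the landmark labels A–D to their ``k_i``.  The
    defaults are derived from the phantom rater model via
    :meth:`from_rater_model` applied to the default
    :class:`~hipmetrics.phantom.RaterModel` at the default phantom scale —
    the same construction used for the reference human-pose constants,
    where ``k_i`` is twice the per-keypoint labeling standard deviation
    divided by object scale.  ``uniform(k)`` gives the flat fallback.
    """

    per_label: dict = field(
        default_factory=lambda: {"A": 0.030, "B": 0.023, "C": 0.038, "D": 0.061}
    )

    def __post_init__(self) -> None:
        if set(self.per_label) != {"A", "B", "C", "D"}:
            raise ValueError("per_label must map exactly the labels A, B, C, D")
        if any(v <= 0 for v in self.per_label.values()):
            raise ValueError("all falloff constants must be positive")

    def k_vector(self) -> np.ndarray:
        """(8,) falloffs in canonical keypoint order (R-A..R-D, L-A..L-D)."""
        return np.array([self.per_label[name[-1]] for name in KEYPOINT_ORDER])

    @classmethod
    def uniform(cls, k: float = 0.05) -> "OKSConfig":
        return cls({lab: k for lab in "ABCD"})

    @classmethod
    def from_rater_model(cls, rater: RaterModel, object_scale: float) -> "OKSConfig":
        """k_i = 2 * sigma_i / s, mirroring how human-variability constants are set."""
        if object_scale <= 0:
            raise ValueError("object scale must be positive")
        return cls(
            {lab: 2.0 * rater.sigma(lab) / object_scale for lab in "ABCD"}
        )


@dataclass(frozen=True)
class DetectionPR:
    """Precision/recall on the OKS threshold grid, and their means."""

    thresholds: tuple
    precision: tuple
    recall: tuple
    map: float
    mar: float


@dataclass(frozen=True)
class AgreementReport:
    """ICC with CI plus Bland-Altman agreement between two measurement sets."""

    icc: float
    icc_ci: tuple[float, float]
    bias: float
    loa_lower: float
    loa_upper: float
    n: int


# ---------------------------------------------------------------------------
# OKS and detection PR
# ---------------------------------------------------------------------------

def oks(
    pred: PelvisAnnotation, truth: PelvisAnnotation, cfg: OKSConfig | None = None
) -> tuple[np.ndarray, float]:
    """Per-keypoint OKS similarities and their mean for one detection.

    Object scale is the square root of the ground-truth box area; all 8
    keypoints are visible by construction, so the object OKS is their
    unweighted mean.
    """
    cfg = cfg or OKSConfig()
    area = truth.bbox[2] * truth.bbox[3]
    if area <= 0:
        raise ValueError("ground-truth box has zero area; OKS undefined")
    d2 = np.sum((pred.coords() - truth.coords()) ** 2, axis=1)
    k = cfg.k_vector()
    sims = np.exp(-d2 / (2.0 * area * k**2))
    return sims, float(sims.mean())


def pr_at_threshold(
    predictions: Sequence[PelvisAnnotation | None],
    truths: Sequence[PelvisAnnotation],
    threshold: float,
    cfg: OKSConfig | None = None,
) -> tuple[float, float]:
    """Keypoint-level precision and recall at one OKS threshold.

    Each of the 8 keypoints of each image contributes independently: a true
    positive when its similarity strictly exceeds the threshold, otherwise
    a false negative.  A missing detection (``None`` prediction) contributes
    8 false negatives and no prediction; predictions for images with no
    ground truth would count as false positives (they cannot arise from the
    single-pelvis pipeline but the accounting supports them).
    """
    if len(predictions) != len(truths):
        raise ValueError("prediction and truth lists must align")
    tp = fp = fn = 0
    for pred, truth in zip(predictions, truths):
        if truth is None:
            if pred is not None:
                fp += len(pred.keypoints)
            continue
        if pred is None:
            fn += len(truth.keypoints)
            continue
        sims, _ = oks(pred, truth, cfg)
        hits = int(np.sum(sims > threshold))
        tp += hits
        fn += len(sims) - hits
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    return precision, recall


def map_mar(
    predictions: Sequence[PelvisAnnotation | None],
    truths: Sequence[PelvisAnnotation],
    cfg: OKSConfig | None = None,
) -> DetectionPR:
    """Mean average precision/recall over the 10-point OKS threshold grid."""
    ps, rs = [], []
    for t in OKS_THRESHOLDS:
        p, r = pr_at_threshold(predictions, truths, t, cfg)
        ps.append(p)
        rs.append(r)
    return DetectionPR(
        thresholds=OKS_THRESHOLDS,
        precision=tuple(ps),
        recall=tuple(rs),
        map=float(np.mean(ps)),
        mar=float(np.mean(rs)),
    )


# ---------------------------------------------------------------------------
# Agreement statistics
# ---------------------------------------------------------------------------

def icc(ratings: np.ndarray) -> tuple[float, tuple[float, float]]:
    """ICC(2,1): two-way random effects, absolute agreement, single measurement.

    ``ratings`` is an (n subjects x m raters) matrix with no missing cells;
    returns the coefficient and its 95% F-distribution confidence interval.
    """
    ratings = np.asarray(ratings, dtype=float)
    if ratings.ndim != 2:
        raise ValueError("ratings must be a 2-D subjects-by-raters matrix")
    n, m = ratings.shape
    if n < 3 or m < 2:
        raise ValueError("ICC needs at least 3 subjects and 2 raters")
    if np.isnan(ratings).any():
        raise ValueError("ratings contain missing cells; ICC requires complete data")
    if np.allclose(ratings.var(axis=1).sum() + ratings.var(axis=0).sum(), 0.0):
        raise ValueError("ratings are constant; ICC undefined (zero variance)")

    import pingouin as pg

    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), m),
            "rater": np.tile(np.arange(m), n),
            "score": ratings.ravel(),
        }
    )
    table = pg.intraclass_corr(
        data=long, targets="subject", raters="rater", ratings="score"
    ).set_index("Type")
    # two-way random, absolute agreement, single measurement
    key = "ICC(A,1)" if "ICC(A,1)" in table.index else "ICC2"
    row = table.loc[key]
    ci_col = "CI95" if "CI95" in table.columns else "CI95%"
    lo, hi = row[ci_col]
    return float(row["ICC"]), (float(lo), float(hi))


def bland_altman(a: Sequence[float], b: Sequence[float]) -> dict:
    """Bland-Altman agreement: bias, 95% limits, and the (mean, diff) points.

    Differences are ``a - b``; limits are ``bias +/- 1.96 sd`` with the
    sample (ddof=1) standard deviation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("measurement vectors must have equal length")
    if a.size < 2:
        raise ValueError("Bland-Altman needs at least two pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return {
        "bias": bias,
        "loa_lower": bias - 1.96 * sd,
        "loa_upper": bias + 1.96 * sd,
        "sd": sd,
        "points": np.column_stack([(a + b) / 2.0, d]),
    }


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U with two-sided p (exact for small untied samples)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    method = "exact" if (x.size + y.size <= 12 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Sensitivity harness
# ---------------------------------------------------------------------------

def sensitivity_table(
    dataset,
    configurations: Sequence[DetectorConfig],
    train_config: TrainConfig | None = None,
    *,
    test_dataset=None,
    oks_config: OKSConfig | None = None,
) -> pd.DataFrame:
    """Train and evaluate each detector configuration on identical splits.

    Emits one row per configuration with mAP and mAR on the test set (the
    training dataset's held-out validation images when no ``test_dataset``
    is given).  A configuration whose training fails contributes a row with
    NaN metrics and the error message; the remaining rows still run.
    """
    if len(configurations) == 0:
        raise ValueError("need at least one configuration")
    tc = train_config or TrainConfig()
    rows = []
    for cfg in configurations:
        label = (
            f"{cfg.backbone}+{'FL' if cfg.focal_gamma > 0 else 'CEL'}"
            f"+{'BM' if cfg.target_mask_kind == 'one-hot' else 'HM'}"
        )
        try:
            model, _ = train_detector(dataset, tc, cfg)
            eval_ds = test_dataset if test_dataset is not None else dataset
            preds = [model.predict(img) for img in eval_ds.images]
            pr = map_mar(preds, eval_ds.ground_truth, oks_config)
            rows.append(
                {"configuration": label, "backbone": cfg.backbone,
                 "gamma": cfg.focal_gamma, "mask": cfg.target_mask_kind,
                 "mAP": pr.map, "mAR": pr.mar, "error": ""}
            )
        except Exception as err:  # keep evaluating the remaining rows
            rows.append(
                {"configuration": label, "backbone": cfg.backbone,
                 "gamma": cfg.focal_gamma, "mask": cfg.target_mask_kind,
                 "mAP": float("nan"), "mAR": float("nan"), "error": str(err)}
            )
    return pd.DataFrame(rows)
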