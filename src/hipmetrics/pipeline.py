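"""End-to-end orchestration: image → keypoints → angles → explainable diagnosis.

`run_pipeline` chains the trained detector, the angle geometry, and the
weighted scoring system into a :class:`DiagnosisReport` whose per-side
breakdown (detected keypoints, angles to one decimal, per-angle category
and score, total, decision) makes every diagnosis re-derivable from its own
printed numbers — the explainability contract of the system.
`render_overlay` draws the landmarks, reference lines, and angle rays on
the radiograph with a textual result block, highlighting angles outside
the normal range.  `run_crossval_experiment` trains k fold models,
ensembles their angle measurements per hip (arithmetic mean), and reports
the diagnostic confusion matrix and F1 with a bootstrap confidence
interval.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw

from .detector import DetectorConfig, KeypointDetector, TrainConfig, crossval_train
from .geometry import (
    LABELS,
    SIDES,
    AngleMeasurements,
    GeometryError,
    PelvisAnnotation,
    horizontal_reference,
    measure_hips,
    vertical_reference,
)
from .scoring import (
    ANGLES,
    CategoryCriteria,
    ScoringParams,
    diagnose_from_angles,
    ensemble_measurements,
    f1_score,
)

__all__ = [
    "SideReport",
    "DiagnosisReport",
    "run_pipeline",
    "report_from_annotation",
    "render_overlay",
    "run_crossval_experiment",
    "CrossvalResult",
]


@dataclass
class SideReport:
    """One hip's detected landmarks, angles, categories, scores, and decision."""

    side: str
    keypoints: dict  # label -> (x, y)
    angles_deg: dict  # angle name -> float (full precision)
    categories: dict  # angle name -> category
    scores: dict  # angle name -> int
    total_score: int
    diagnosis: str  # "DDH present" / "DDH absent"
    flags: list  # angle names outside the normal range

    def angles_display(self) -> dict:
        """Angles rounded to 1 decimal degree for reporting."""
        return {k: round(v, 1) for k, v in self.angles_deg.items()}


@dataclass
class DiagnosisReport:
    image_id: str
    status: str  # "ok" or "no detection"
    sides: dict  # side -> SideReport (empty when status != ok)
    threshold: int
    provenance: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            raise TypeError(type(o))

        text = json.dumps(dataclasses.asdict(self), default=enc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def report_from_annotation(
    annotation: PelvisAnnotation,
    criteria: CategoryCriteria | None = None,
    params: ScoringParams | None = None,
    provenance: dict | None = None,
) -> DiagnosisReport:
    """Build the full diagnosis report from an (arbitrary-origin) annotation."""
    criteria = criteria or CategoryCriteria()
    params = params or ScoringParams()
    measurements = measure_hips(annotation)
    sides = {}
    for side in SIDES:
        raw = measurements[side]
        # the report is the clinical display artifact: angles are carried at
        # 1 decimal and the diagnosis is derived from those same printed
        # values, so every report is exactly re-derivable from its own text
        m = AngleMeasurements(
            side=side,
            ce_deg=round(raw.ce_deg, 1),
            tonnis_deg=round(raw.tonnis_deg, 1),
            sharp_deg=round(raw.sharp_deg, 1),
        )
        diag = diagnose_from_angles(m, criteria, params)
        flags = [a for a, (cat, _) in diag.breakdown.items() if cat != "normal"]
        sides[side] = SideReport(
            side=side,
            keypoints={lab: (annotation.get(side, lab).x, annotation.get(side, lab).y) for lab in LABELS},
            angles_deg={"ce": m.ce_deg, "tonnis": m.tonnis_deg, "sharp": m.sharp_deg},
            categories={a: cat for a, (cat, _) in diag.breakdown.items()},
            scores={a: s for a, (_, s) in diag.breakdown.items()},
            total_score=diag.total_score,
            diagnosis=diag.label,
            flags=flags,
        )
    return DiagnosisReport(
        image_id=annotation.image_id,
        status="ok",
        sides=sides,
        threshold=params.threshold,
        provenance=provenance or {},
    )


def run_pipeline(
    image: np.ndarray,
    model: KeypointDetector,
    criteria: CategoryCriteria | None = None,
    params: ScoringParams | None = None,
    image_id: str = "0",
    provenance: dict | None = None,
) -> DiagnosisReport:
    """Detect landmarks, measure angles, and score one radiograph.

    A detector failure (no usable detection, degenerate landmark geometry)
    yields a structured "no detection" report rather than an exception.
    """
    params = params or ScoringParams()
    prov = {"model": f"{model.config.backbone}/{model.config.mask_resolution}", **(provenance or {})}
    try:
        annotation = model.predict(image)
        annotation.image_id = image_id
        report = report_from_annotation(annotation, criteria, params, prov)
        return report
    except (GeometryError, ValueError, FloatingPointError) as err:
        return DiagnosisReport(
            image_id=image_id,
            status="no detection",
            sides={},
            threshold=params.threshold,
            provenance={**prov, "error": str(err)},
        )


# ---------------------------------------------------------------------------
# Overlay rendering
# ---------------------------------------------------------------------------

_NORMAL_COLOR = (90, 200, 120)
_FLAG_COLOR = (230, 60, 60)
_LINE_COLORS = {"ce": (80, 140, 255), "tonnis": (90, 200, 120), "sharp": (200, 120, 230)}


def render_overlay(image: np.ndarray, report: DiagnosisReport) -> np.ndarray:
    """Annotated image: keypoints, reference lines, angle rays, result text.

    The text block is appended below the radiograph (output is taller than
    the input); angles outside the normal range are printed in the highlight
    color.  Raises when the report does not refer to this image.
    """
    if report.status != "ok":
        raise ValueError("cannot render an overlay for a report without detections")
    h, w = image.shape[:2]
    for side_rep in report.sides.values():
        for x, y in side_rep.keypoints.values():
            if not (0 <= x < w and 0 <= y < h):
                raise ValueError("report keypoints fall outside this image; mismatched pair?")

    text_h = 60
    canvas = Image.new("RGB", (w, h + text_h), (0, 0, 0))
    canvas.paste(Image.fromarray(image).convert("RGB"), (0, 0))
    draw = ImageDraw.Draw(canvas)

    kp = {(s, lab): report.sides[s].keypoints[lab] for s in report.sides for lab in LABELS}
    # inter-teardrop horizontal reference, extended across the image
    (ax_r, ay_r), (ax_l, ay_l) = kp[("right", "A")], kp[("left", "A")]
    d = np.array([ax_l - ax_r, ay_l - ay_r], dtype=float)
    d /= max(np.hypot(*d), 1e-9)
    p0 = np.array([ax_r, ay_r]) - d * w
    p1 = np.array([ax_r, ay_r]) + d * w
    draw.line([tuple(p0), tuple(p1)], fill=(220, 220, 100), width=1)
    for side, rep in report.sides.items():
        b = np.array(kp[(side, "B")])
        n = np.array([d[1], -d[0]])
        draw.line([tuple(b - 60 * n), tuple(b + 30 * n)], fill=(120, 170, 240), width=1)
        segs = {"ce": ("B", "C"), "tonnis": ("D", "C"), "sharp": ("A", "C")}
        for angle_name, (l0, l1) in segs.items():
            draw.line([kp[(side, l0)], kp[(side, l1)]], fill=_LINE_COLORS[angle_name], width=2)
        for lab in LABELS:
            x, y = kp[(side, lab)]
            draw.ellipse([x - 3, y - 3, x + 3, y + 3], outline=(255, 255, 255), width=1)

    y_text = h + 4
    for side in ("right", "left"):
        rep = report.sides[side]
        disp = rep.angles_display()
        parts = [f"{side[0].upper()}:"]
        for a, name in (("ce", "CE"), ("tonnis", "Tonnis"), ("sharp", "Sharp")):
            parts.append(f"{name} {disp[a]:.1f} ({rep.scores[a]})")
        parts.append(f"total {rep.total_score} -> {rep.diagnosis}")
        color = _FLAG_COLOR if rep.diagnosis == "DDH present" else _NORMAL_COLOR
        draw.text((6, y_text), "  ".join(parts), fill=color)
        y_text += 14
    flagged = [
        f"{s[0].upper()}-{a}" for s, rep in report.sides.items() for a in rep.flags
    ]
    if flagged:
        draw.text((6, y_text), "outside normal: " + ", ".join(flagged), fill=_FLAG_COLOR)
    return np.asarray(canvas)


# ---------------------------------------------------------------------------
# Cross-validation experiment
# ---------------------------------------------------------------------------

@dataclass
class CrossvalResult:
    confusion: np.ndarray  # rows = truth, cols = prediction, [neg, pos]
    f1: float
    f1_ci: tuple[float, float]
    per_fold_f1: list
    ensemble_table: pd.DataFrame  # image_id, side, angles, prediction, label


def run_crossval_experiment(
    dataset,
    test_dataset,
    k: int = 10,
    seed: int = 0,
    train_config: TrainConfig | None = None,
    detector_config: DetectorConfig | None = None,
    criteria: CategoryCriteria | None = None,
    params: ScoringParams | None = None,
    n_bootstrap: int = 1000,
) -> CrossvalResult:
    """Train k fold models, ensemble their angle measurements, and diagnose.

    Each fold model measures every test image; per hip, the angle
    measurements are averaged across the k models before scoring.  The
    confusion matrix has truth in rows and prediction in columns with
    "DDH present" as the positive class; the F1 confidence interval is a
    percentile bootstrap over test hips (seeded).
    """
    tc = train_config or TrainConfig()
    tc = dataclasses.replace(tc, seed=seed)
    criteria = criteria or CategoryCriteria()
    params = params or ScoringParams()
    models, _ = crossval_train(dataset, k=k, train_config=tc, config=detector_config)

    labels = {
        (row["image_id"], row["side"]): int(row["label"])
        for _, row in test_dataset.angle_table.iterrows()
    }
    rows = []
    per_model_preds: list[list[int]] = [[] for _ in models]
    truths: list[int] = []
    for img, gt in zip(test_dataset.images, test_dataset.ground_truth):
        per_side: dict[str, list[AngleMeasurements]] = {s: [] for s in SIDES}
        for mi, model in enumerate(models):
            try:
                ann = model.predict(img)
                measures = measure_hips(ann)
            except (GeometryError, ValueError):
                measures = None
            for side in SIDES:
                if measures is not None:
                    per_side[side].append(measures[side])
        for side in SIDES:
            if not per_side[side]:
                continue
            truth = labels[(gt.image_id, side)]
            truths.append(truth)
            for mi, m in enumerate(per_side[side]):
                per_model_preds[mi].append(
                    int(diagnose_from_angles(m, criteria, params).positive)
                )
            ens = ensemble_measurements(per_side[side])
            diag = diagnose_from_angles(ens, criteria, params)
            rows.append(
                {
                    "image_id": gt.image_id,
                    "side": side,
                    "ce_deg": ens.ce_deg,
                    "tonnis_deg": ens.tonnis_deg,
                    "sharp_deg": ens.sharp_deg,
                    "prediction": int(diag.positive),
                    "label": truth,
                }
            )
    table = pd.DataFrame(rows)
    pred = table["prediction"].to_numpy()
    true = table["label"].to_numpy()
    confusion = np.array(
        [
            [int(np.sum((true == 0) & (pred == 0))), int(np.sum((true == 0) & (pred == 1)))],
            [int(np.sum((true == 1) & (pred == 0))), int(np.sum((true == 1) & (pred == 1)))],
        ]
    )
    f1 = f1_score(pred, true)
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_bootstrap):
        idx = rng.integers(0, len(true), len(true))
        if true[idx].sum() == 0 and pred[idx].sum() == 0:
            continue
        boots.append(f1_score(pred[idx], true[idx]))
    ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    per_fold = [
        f1_score(np.asarray(p), np.asarray(truths)) for p in per_model_preds if len(p) == len(truths)
    ]
    return CrossvalResult(confusion, f1, ci, per_fold, table)
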