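"""Radiographic reference lines and hip angles from pelvic landmarks.

The clinical measurements implemented here are the three standard indices of
acetabular coverage and inclination on an anteroposterior pelvic radiograph:

* **Center-Edge (CE) angle of Wiberg** — between the line from the femoral
  head center (B) to the lateral acetabular edge (C) and the vertical
  reference line through B.
* **Tönnis angle** (acetabular index) — between the line from the medial
  acetabular aspect (D) to C and the horizontal direction through D.
* **Sharp angle** (acetabular angle) — between the line from the teardrop's
  inferior boundary (A) to C and the inter-teardrop horizontal.

The horizontal reference line connects the two teardrop points (the A
landmarks of both hips); the vertical reference is its perpendicular through
B.  All angles are therefore invariant under rigid rotation and uniform
scaling of the full landmark set.

Coordinate conventions: raster image coordinates, origin at the top-left
corner, x increasing rightward, y increasing downward; "superior" anatomy is
smaller y.  The patient's right hip occupies the left half of the image
(standard AP view), so "lateral" is the -x direction for the right hip and
+x for the left hip when the image is upright.

Sign conventions (a documented superset of the clinical magnitudes):

* CE is positive when C is lateral to the vertical reference (normal
  coverage) and negative when C is medial (severe dysplasia).
* Tönnis is positive when C is superior to D (upward sourcil inclination).
* Sharp is the unsigned acute angle between line AC and the horizontal.

All angles are computed with two-argument arctangents on direction vectors;
there are no divisions by coordinate differences and hence no singular
orientations.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "LABELS",
    "SIDES",
    "KEYPOINT_ORDER",
    "Keypoint",
    "Line2D",
    "PelvisAnnotation",
    "AngleMeasurements",
    "horizontal_reference",
    "vertical_reference",
    "ce_angle",
    "tonnis_angle",
    "sharp_angle",
    "measure_hips",
    "read_coco_annotations",
    "write_coco_annotations",
    "write_angle_csv",
    "read_angle_csv",
]

LABELS = ("A", "B", "C", "D")
SIDES = ("right", "left")
#: Canonical keypoint ordering used in COCO categories and detector channels.
KEYPOINT_ORDER = tuple(f"{s[0].upper()}-{lab}" for s in SIDES for lab in LABELS)


class GeometryError(ValueError):
    """Degenerate landmark configuration (coincident or missing points)."""


@dataclass(frozen=True)
class Keypoint:
    """A named anatomical landmark in image pixel coordinates."""

    x: float
    y: float
    label: str
    side: str

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise GeometryError(f"non-finite keypoint {self.side}-{self.label}")
        if self.label not in LABELS:
            raise GeometryError(f"unknown keypoint label {self.label!r}")
        if self.side not in SIDES:
            raise GeometryError(f"unknown side {self.side!r}")

    @property
    def xy(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass(frozen=True)
class Line2D:
    """A line given by a point and a unit direction vector."""

    point: tuple[float, float]
    direction: tuple[float, float]

    def __post_init__(self) -> None:
        norm = math.hypot(*self.direction)
        if not math.isclose(norm, 1.0, rel_tol=0, abs_tol=1e-9):
            raise GeometryError("Line2D direction must be a unit vector")

    @property
    def d(self) -> np.ndarray:
        return np.array(self.direction, dtype=float)

    def distance(self, p: Sequence[float]) -> float:
        """Perpendicular distance from ``p`` to the line."""
        v = np.asarray(p, dtype=float) - np.asarray(self.point, dtype=float)
        dx, dy = self.direction
        return abs(dx * float(v[1]) - dy * float(v[0]))


@dataclass
class PelvisAnnotation:
    """Eight landmarks (A–D on each hip) plus one pelvis bounding box.

    ``bbox`` is ``(x, y, w, h)`` with top-left origin.  Keypoints are stored
    in canonical order (right A–D, then left A–D) regardless of insertion
    order.
    """

    keypoints: list[Keypoint]
    bbox: tuple[float, float, float, float]
    image_id: str = "0"

    def __post_init__(self) -> None:
        slots = {(k.side, k.label) for k in self.keypoints}
        expected = {(s, lab) for s in SIDES for lab in LABELS}
        if slots != expected or len(self.keypoints) != 8:
            missing = sorted(expected - slots)
            raise GeometryError(
                f"annotation must contain each side/label exactly once; missing {missing}"
            )
        order = {(s, lab): i for i, (s, lab) in enumerate((s, lab) for s in SIDES for lab in LABELS)}
        self.keypoints = sorted(self.keypoints, key=lambda k: order[(k.side, k.label)])
        x, y, w, h = self.bbox
        if w <= 0 or h <= 0:
            raise GeometryError("bounding box must have positive width and height")

    def get(self, side: str, label: str) -> Keypoint:
        for k in self.keypoints:
            if k.side == side and k.label == label:
                return k
        raise KeyError((side, label))

    def coords(self) -> np.ndarray:
        """(8, 2) array of keypoint coordinates in canonical order."""
        return np.array([[k.x, k.y] for k in self.keypoints], dtype=float)

    @classmethod
    def from_coords(
        cls,
        coords: np.ndarray,
        bbox: tuple[float, float, float, float],
        image_id: str = "0",
    ) -> "PelvisAnnotation":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (8, 2):
            raise GeometryError(f"expected (8, 2) coordinates, got {coords.shape}")
        kps = [
            Keypoint(float(coords[i, 0]), float(coords[i, 1]), lab, s)
            for i, (s, lab) in enumerate((s, lab) for s in SIDES for lab in LABELS)
        ]
        return cls(kps, bbox, image_id)

    def transformed(self, fn) -> "PelvisAnnotation":
        """Apply ``fn((n,2) array) -> (n,2) array`` to keypoints and bbox corners."""
        new = fn(self.coords())
        x, y, w, h = self.bbox
        corners = fn(np.array([[x, y], [x + w, y], [x, y + h], [x + w, y + h]], float))
        bx, by = corners.min(axis=0)
        bw, bh = corners.max(axis=0) - corners.min(axis=0)
        return PelvisAnnotation.from_coords(new, (float(bx), float(by), float(bw), float(bh)), self.image_id)


@dataclass(frozen=True)
class AngleMeasurements:
    """CE, Tönnis, and Sharp angles (degrees) for one hip side."""

    side: str
    ce_deg: float
    tonnis_deg: float
    sharp_deg: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.ce_deg, self.tonnis_deg, self.sharp_deg)


# ---------------------------------------------------------------------------
# Reference lines
# ---------------------------------------------------------------------------

def horizontal_reference(a_right: Keypoint, a_left: Keypoint) -> Line2D:
    """Inter-teardrop line through both A landmarks.

    Direction is normalized with a positive x component so that downstream
    lateral/superior decompositions are deterministic.
    """
    v = a_left.xy - a_right.xy
    n = float(np.hypot(*v))
    if n < 1e-12:
        raise GeometryError("teardrop points coincide; horizontal reference undefined")
    d = v / n
    if d[0] < 0:
        d = -d
    return Line2D((a_right.x, a_right.y), (float(d[0]), float(d[1])))


def vertical_reference(href: Line2D, b: Keypoint) -> Line2D:
    """Perpendicular to the horizontal reference, through the femoral head center B."""
    ux, uy = href.direction
    # rotate by -90 deg in raster coordinates -> points superior (smaller y)
    return Line2D((b.x, b.y), (uy, -ux))


def _frame(href: Line2D, side: str) -> tuple[np.ndarray, np.ndarray]:
    """Unit (lateral, superior) directions for ``side`` given the horizontal reference."""
    u = href.d
    up = np.array([u[1], -u[0]])  # superior: -y when href is +x
    lat = -u if side == "right" else u
    return lat, up


# ---------------------------------------------------------------------------
# Angles
# ---------------------------------------------------------------------------

def ce_angle(b: Keypoint, c: Keypoint, href: Line2D) -> float:
    """Center-Edge angle (degrees): B→C versus the vertical reference through B.

    Positive when C is lateral to the vertical line, negative when medial.
    Anatomically plausible configurations (C superior to B) fall in
    (-90, 90); an inferior C yields |angle| > 90 and is reported as-is.
    """
    if b.side != c.side:
        raise GeometryError("CE angle requires B and C from the same hip")
    v = c.xy - b.xy
    if float(np.hypot(*v)) < 1e-12:
        raise GeometryError(f"coincident B and C on {b.side} hip")
    lat, up = _frame(href, b.side)
    return math.degrees(math.atan2(float(v @ lat), float(v @ up)))


def tonnis_angle(c: Keypoint, d: Keypoint, href: Line2D) -> float:
    """Tönnis angle (degrees): D→C versus the horizontal direction through D.

    Positive when C is superior to D (the usual superolateral inclination of
    the acetabular sourcil), negative when inferior.
    """
    if c.side != d.side:
        raise GeometryError("Tönnis angle requires C and D from the same hip")
    v = c.xy - d.xy
    if float(np.hypot(*v)) < 1e-12:
        raise GeometryError(f"coincident C and D on {c.side} hip")
    lat, up = _frame(href, c.side)
    return math.degrees(math.atan2(float(v @ up), float(v @ lat)))


def sharp_angle(a: Keypoint, c: Keypoint, href: Line2D) -> float:
    """Sharp angle (degrees): acute angle between line AC and the horizontal.

    Unsigned (range [0, 90]); invariant to exchanging A and C since it is an
    angle between lines, not rays.
    """
    if a.side != c.side:
        raise GeometryError("Sharp angle requires A and C from the same hip")
    v = c.xy - a.xy
    if float(np.hypot(*v)) < 1e-12:
        raise GeometryError(f"coincident A and C on {a.side} hip")
    u = href.d
    along = abs(float(v @ u))
    across = abs(float(u[0] * v[1] - u[1] * v[0]))
    return math.degrees(math.atan2(across, along))


def measure_hips(annotation: PelvisAnnotation) -> dict[str, AngleMeasurements]:
    """Measure CE, Tönnis, and Sharp on both hips of one annotation.

    The horizontal reference is shared (inter-teardrop line); each side's
    vertical reference passes through its own femoral head center.

    Returns a mapping ``{"right": AngleMeasurements, "left": ...}``.
    """
    href = horizontal_reference(annotation.get("right", "A"), annotation.get("left", "A"))
    out: dict[str, AngleMeasurements] = {}
    for side in SIDES:
        a, b, c, d = (annotation.get(side, lab) for lab in LABELS)
        try:
            out[side] = AngleMeasurements(
                side=side,
                ce_deg=ce_angle(b, c, href),
                tonnis_deg=tonnis_angle(c, d, href),
                sharp_deg=sharp_angle(a, c, href),
            )
        except GeometryError as err:
            raise GeometryError(f"{side} hip: {err}") from err
    return out


# ---------------------------------------------------------------------------
# COCO-style keypoint JSON and angle CSV I/O
# ---------------------------------------------------------------------------

_CATEGORY = {
    "id": 1,
    "name": "pelvis",
    "supercategory": "pelvis",
    "keypoints": list(KEYPOINT_ORDER),
    "skeleton": [],
}


def write_coco_annotations(
    annotations: Iterable[PelvisAnnotation],
    path: str | Path,
    image_sizes: Mapping[str, tuple[int, int]] | None = None,
    file_names: Mapping[str, str] | None = None,
) -> None:
    """Write annotations as a COCO keypoint JSON file.

    ``image_sizes`` maps image_id -> (height, width); ``file_names`` maps
    image_id -> file name (defaults to ``<image_id>.png``).
    """
    images, anns = [], []
    for i, ann in enumerate(annotations):
        h, w = (image_sizes or {}).get(ann.image_id, (0, 0))
        fname = (file_names or {}).get(ann.image_id, f"{ann.image_id}.png")
        images.append({"id": ann.image_id, "height": h, "width": w, "file_name": fname})
        flat: list[float] = []
        for k in ann.keypoints:
            flat.extend([k.x, k.y, 2])  # v=2: labeled and visible
        anns.append(
            {
                "id": i + 1,
                "image_id": ann.image_id,
                "category_id": 1,
                "bbox": list(map(float, ann.bbox)),
                "keypoints": flat,
                "num_keypoints": 8,
                "iscrowd": 0,
                "area": float(ann.bbox[2] * ann.bbox[3]),
            }
        )
    payload = {"images": images, "annotations": anns, "categories": [_CATEGORY]}
    Path(path).write_text(json.dumps(payload, indent=1))


def read_coco_annotations(path: str | Path) -> list[PelvisAnnotation]:
    """Read pelvis annotations from a COCO keypoint JSON file."""
    payload = json.loads(Path(path).read_text())
    cats = {c["id"]: c for c in payload.get("categories", [])}
    out = []
    for ann in payload["annotations"]:
        names = cats.get(ann.get("category_id", 1), _CATEGORY)["keypoints"]
        if list(names) != list(KEYPOINT_ORDER):
            raise GeometryError(f"unexpected keypoint ordering in {path}")
        flat = ann["keypoints"]
        coords = np.array(flat, dtype=float).reshape(8, 3)[:, :2]
        bbox = tuple(float(v) for v in ann["bbox"])
        out.append(PelvisAnnotation.from_coords(coords, bbox, str(ann["image_id"])))
    return out


def write_angle_csv(
    rows: Iterable[tuple[str, AngleMeasurements]],
    path: str | Path,
    labels: Mapping[tuple[str, str], int] | None = None,
) -> None:
    """Write per-hip angles as CSV (image_id, side, ce_deg, tonnis_deg, sharp_deg[, label])."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        header = ["image_id", "side", "ce_deg", "tonnis_deg", "sharp_deg"]
        if labels is not None:
            header.append("label")
        writer.writerow(header)
        for image_id, m in rows:
            row = [image_id, m.side, f"{m.ce_deg:.6f}", f"{m.tonnis_deg:.6f}", f"{m.sharp_deg:.6f}"]
            if labels is not None:
                row.append(str(labels[(image_id, m.side)]))
            writer.writerow(row)


def read_angle_csv(path: str | Path):
    """Read an angle table CSV into a pandas DataFrame."""
    import pandas as pd

    return pd.read_csv(path, dtype={"image_id": str})
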