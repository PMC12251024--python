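"""Synthetic pelvic-radiograph phantoms with exactly known landmarks and angles.

Real annotated pelvic radiographs are hospital data and are not shipped; the
phantom generator stands in for them.  It produces grayscale images built
from smooth high-contrast primitives (a cone-profile disc for each femoral
head, a thick sourcil ridge from the medial acetabular aspect to the lateral
edge, a compact teardrop blob, and a faint pelvic-brim ellipse for context)
whose generating coordinates ARE the ground-truth landmarks, so every
detection and measurement result can be checked against an exact answer.

Landmark construction is analytic and guarantees exact angle round-trips:
the teardrop points (A) of both hips are placed on a horizontal line, the
femoral head center (B) at a fixed offset from A, and the lateral acetabular
edge (C) — shared by all three angles — is solved as the intersection of the
CE-angle ray from B and the Sharp-angle ray from A.  The medial aspect (D)
is then placed on the line through C at the Tönnis angle below the
horizontal, at a fixed fraction of the inter-teardrop distance.  Any
requested (CE, Sharp) pair whose rays fail to intersect with positive ray
parameters is rejected as geometrically infeasible.

Annotator variability is emulated by a :class:`RaterModel`: each simulated
rater re-labels every landmark with independent Gaussian jitter whose
standard deviation depends on the landmark, the medial acetabular aspect (D)
being the least reproducible landmark (sigma 2–3x that of the femoral head
center), as observed in repeated expert annotations.  The consensus
annotation is the mean of the replicates, mirroring the averaging of
multiple expert annotators.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

from .geometry import (
    LABELS,
    SIDES,
    AngleMeasurements,
    Keypoint,
    PelvisAnnotation,
    measure_hips,
    read_coco_annotations,
    write_coco_annotations,
)
from .scoring import CategoryCriteria, ScoringParams, diagnose_from_angles

__all__ = [
    "PhantomConfig",
    "RaterModel",
    "PhantomDataset",
    "construct_landmarks",
    "render_phantom",
    "sample_angles",
    "generate_dataset",
    "save_dataset",
    "load_dataset",
]

# Fixed anatomical proportions of the phantom, as fractions of the
# inter-teardrop separation (chosen once from adult AP-radiograph anatomy:
# femoral head centered ~1/3 of the inter-teardrop distance lateral to the
# teardrop, sourcil length ~1/4 of it).
_B_LATERAL = 0.30   # femoral head center: lateral offset from A
_B_SUPERIOR = 0.04  # femoral head center: superior offset from A
_CD_LENGTH = 0.25   # sourcil length |CD|
_TEARDROP_ROW = 0.55  # y of the inter-teardrop line, fraction of image height
_BBOX_PAD = 0.10    # bounding-box padding, fraction of the tight-box diagonal

#: n_images below which missing angle categories warn instead of raising.
SMALL_N_THRESHOLD = 20


class PhantomGeometryError(ValueError):
    """Requested angle triple admits no consistent landmark placement."""


@dataclass(frozen=True)
class PhantomConfig:
    """Target geometry of one phantom radiograph.

    Angles may be a single float (both hips identical) or a ``(right, left)``
    pair, in degrees.  All lengths are pixels.  ``rotation_deg`` rigidly
    rotates the whole pelvis about the image center (angles are invariant to
    it since the reference lines rotate along).
    """

    image_height: int = 256
    image_width: int = 256
    ce_deg: float | tuple[float, float] = 30.0
    tonnis_deg: float | tuple[float, float] = 5.0
    sharp_deg: float | tuple[float, float] = 38.0
    femoral_head_radius: float = 20.0
    teardrop_separation: float = 110.0
    noise_sigma: float = 4.0
    rotation_deg: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height < 64 or self.image_width < 64:
            raise ValueError("image dimensions must be at least 64 pixels")
        if not (0 < self.teardrop_separation < self.image_width):
            raise ValueError("teardrop_separation must be positive and fit in the image")
        for side in SIDES:
            ce, to, sh = self.angles(side)
            if not all(math.isfinite(v) for v in (ce, to, sh)):
                raise ValueError("target angles must be finite")
            if sh <= 0:
                raise ValueError("sharp_deg must be positive")
        if self.femoral_head_radius <= 0:
            raise ValueError("femoral_head_radius must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")

    def _pick(self, v: float | tuple[float, float], side: str) -> float:
        if isinstance(v, (tuple, list)):
            return float(v[0] if side == "right" else v[1])
        return float(v)

    def angles(self, side: str) -> tuple[float, float, float]:
        """(ce, tonnis, sharp) targets for one side, degrees."""
        return (
            self._pick(self.ce_deg, side),
            self._pick(self.tonnis_deg, side),
            self._pick(self.sharp_deg, side),
        )


@dataclass(frozen=True)
class RaterModel:
    """Per-landmark jitter standard deviations (pixels) of a simulated rater.

    Defaults follow the observed reliability ordering of the landmarks: the
    femoral head center (B) is the most reproducible, the medial acetabular
    aspect (D) the least, with sigma about 2.7x that of B.
    """

    sigma_a: float = 2.0
    sigma_b: float = 1.5
    sigma_c: float = 2.5
    sigma_d: float = 4.0
    n_raters: int = 3

    def __post_init__(self) -> None:
        if min(self.sigma_a, self.sigma_b, self.sigma_c, self.sigma_d) < 0:
            raise ValueError("jitter sigmas must be non-negative")
        if self.n_raters < 1:
            raise ValueError("need at least one rater")

    def sigma(self, label: str) -> float:
        return {"A": self.sigma_a, "B": self.sigma_b, "C": self.sigma_c, "D": self.sigma_d}[label]

    @classmethod
    def zero(cls, n_raters: int = 3) -> "RaterModel":
        return cls(0.0, 0.0, 0.0, 0.0, n_raters)


# ---------------------------------------------------------------------------
# Landmark construction
# ---------------------------------------------------------------------------

def _side_landmarks(
    a: np.ndarray,
    lat: np.ndarray,
    up: np.ndarray,
    sep: float,
    ce: float,
    tonnis: float,
    sharp: float,
) -> dict[str, np.ndarray]:
    """Solve one hip's landmarks in the (lateral, superior) frame anchored at A."""
    b = a + _B_LATERAL * sep * lat + _B_SUPERIOR * sep * up
    ce_r, sh_r, to_r = map(math.radians, (ce, sharp, tonnis))
    dir_ce = math.sin(ce_r) * lat + math.cos(ce_r) * up
    dir_sh = math.cos(sh_r) * lat + math.sin(sh_r) * up
    # A + s*dir_sh == B + t*dir_ce ; 2x2 linear solve
    m = np.column_stack([dir_sh, -dir_ce])
    det = float(np.linalg.det(m))
    if abs(det) < 1e-12:
        raise PhantomGeometryError(
            f"CE={ce} and Sharp={sharp} rays are parallel; no lateral edge exists"
        )
    s, t = np.linalg.solve(m, b - a)
    if s <= 1e-9 or t <= 1e-9:
        raise PhantomGeometryError(
            f"CE={ce}, Sharp={sharp} rays do not intersect on the anatomical side "
            f"(ray parameters s={s:.3g}, t={t:.3g})"
        )
    # Near-parallel rays (ce + sharp -> 90 deg) intersect arbitrarily far from
    # the joint: anatomically contradictory coverage/inclination, rejected.
    if s > 0.95 * sep or t > 0.85 * sep:
        raise PhantomGeometryError(
            f"CE={ce}, Sharp={sharp} place the lateral edge unrealistically far "
            f"from the acetabulum (|AC|={s:.0f}px, |BC|={t:.0f}px at separation {sep:.0f}px)"
        )
    c = a + s * dir_sh
    d = c - _CD_LENGTH * sep * (math.cos(to_r) * lat + math.sin(to_r) * up)
    return {"A": a, "B": b, "C": c, "D": d}


def construct_landmarks(config: PhantomConfig) -> PelvisAnnotation:
    """Place the 8 landmarks so the measured angles equal the config targets exactly.

    Raises :class:`PhantomGeometryError` when the requested (CE, Sharp) pair
    is geometrically contradictory, and ``ValueError`` when the solved
    landmarks fall outside the image.
    """
    sep = config.teardrop_separation
    cx = config.image_width / 2.0
    ay = _TEARDROP_ROW * config.image_height
    up = np.array([0.0, -1.0])
    kps: list[Keypoint] = []
    for side in SIDES:
        lat = np.array([-1.0, 0.0]) if side == "right" else np.array([1.0, 0.0])
        a = np.array([cx - sep / 2.0, ay]) if side == "right" else np.array([cx + sep / 2.0, ay])
        pts = _side_landmarks(a, lat, up, sep, *config.angles(side))
        for lab in LABELS:
            kps.append(Keypoint(float(pts[lab][0]), float(pts[lab][1]), lab, side))

    coords = np.array([[k.x, k.y] for k in kps])
    if config.rotation_deg:
        th = math.radians(config.rotation_deg)
        rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        center = np.array([config.image_width / 2.0, config.image_height / 2.0])
        coords = (coords - center) @ rot.T + center
        kps = [
            Keypoint(float(x), float(y), k.label, k.side)
            for (x, y), k in zip(coords, kps)
        ]

    if (
        coords[:, 0].min() < 0
        or coords[:, 1].min() < 0
        or coords[:, 0].max() >= config.image_width
        or coords[:, 1].max() >= config.image_height
    ):
        raise ValueError("constructed landmarks fall outside the image bounds")

    bbox = tight_bbox(coords)
    return PelvisAnnotation(kps, bbox, image_id=str(config.seed))


def tight_bbox(coords: np.ndarray) -> tuple[float, float, float, float]:
    """Tight box around points, padded on all sides by 10% of the box diagonal."""
    x0, y0 = coords.min(axis=0)
    x1, y1 = coords.max(axis=0)
    pad = _BBOX_PAD * math.hypot(x1 - x0, y1 - y0)
    return (float(x0 - pad), float(y0 - pad), float(x1 - x0 + 2 * pad), float(y1 - y0 + 2 * pad))


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _add_segment(img: np.ndarray, p0: np.ndarray, p1: np.ndarray, width: float, amp: float) -> None:
    """Additively draw a soft-edged thick segment (Gaussian cross-profile)."""
    h, w = img.shape
    x0 = max(0, int(min(p0[0], p1[0]) - 4 * width))
    x1 = min(w, int(max(p0[0], p1[0]) + 4 * width) + 1)
    y0 = max(0, int(min(p0[1], p1[1]) - 4 * width))
    y1 = min(h, int(max(p0[1], p1[1]) + 4 * width) + 1)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    pts = np.stack([xx, yy], axis=-1).astype(float)
    seg = p1 - p0
    seg_len2 = float(seg @ seg)
    tproj = np.clip(((pts - p0) @ seg) / max(seg_len2, 1e-12), 0.0, 1.0)
    nearest = p0 + tproj[..., None] * seg
    dist2 = np.sum((pts - nearest) ** 2, axis=-1)
    img[y0:y1, x0:x1] += amp * np.exp(-dist2 / (2.0 * width**2))


def _add_blob(img: np.ndarray, p: np.ndarray, sx: float, sy: float, amp: float) -> None:
    h, w = img.shape
    x0 = max(0, int(p[0] - 4 * sx)); x1 = min(w, int(p[0] + 4 * sx) + 1)
    y0 = max(0, int(p[1] - 4 * sy)); y1 = min(h, int(p[1] + 4 * sy) + 1)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    img[y0:y1, x0:x1] += amp * np.exp(
        -((xx - p[0]) ** 2) / (2 * sx**2) - ((yy - p[1]) ** 2) / (2 * sy**2)
    )


def _add_cone_disc(img: np.ndarray, p: np.ndarray, radius: float, amp: float) -> None:
    """Disc with a linear radial profile peaking exactly at the center."""
    h, w = img.shape
    x0 = max(0, int(p[0] - radius) - 1); x1 = min(w, int(p[0] + radius) + 2)
    y0 = max(0, int(p[1] - radius) - 1); y1 = min(h, int(p[1] + radius) + 2)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    r = np.hypot(xx - p[0], yy - p[1])
    img[y0:y1, x0:x1] += amp * np.clip(1.0 - r / radius, 0.0, None)


def render_phantom(config: PhantomConfig, annotation: PelvisAnnotation) -> np.ndarray:
    """Render an 8-bit grayscale phantom image for an annotation.

    Deterministic given ``config.seed``.  The landmark coordinates of
    ``annotation`` are the ground truth regardless of rendering; rendering
    only places image structure so each landmark has a learnable signature:
    the femoral head disc peaks at B, the sourcil ridge runs from D and ends
    at C (joined there by a short iliac rim segment), and the teardrop blob
    is centered at A.
    """
    h, w = config.image_height, config.image_width
    coords = annotation.coords()
    if (
        coords[:, 0].min() < 0
        or coords[:, 1].min() < 0
        or coords[:, 0].max() >= w
        or coords[:, 1].max() >= h
    ):
        raise ValueError("annotation landmarks fall outside the image bounds")

    img = np.full((h, w), 40.0)
    # faint pelvic brim for context
    a_r, a_l = annotation.get("right", "A").xy, annotation.get("left", "A").xy
    mid = (a_r + a_l) / 2.0
    sep = float(np.hypot(*(a_l - a_r)))
    yy, xx = np.mgrid[0:h, 0:w]
    rr = np.hypot((xx - mid[0]) / (0.85 * sep), (yy - (mid[1] - 0.25 * sep)) / (0.55 * sep))
    img += 25.0 * np.exp(-((rr - 1.0) ** 2) / (2 * 0.08**2))

    for side in SIDES:
        a = annotation.get(side, "A").xy
        b = annotation.get(side, "B").xy
        c = annotation.get(side, "C").xy
        d = annotation.get(side, "D").xy
        _add_cone_disc(img, b, config.femoral_head_radius, 140.0)
        _add_segment(img, d, c, width=2.0, amp=110.0)
        # short iliac rim continuing superomedially from C
        rim_dir = (c - d) / max(float(np.hypot(*(c - d))), 1e-9)
        rim_normal = np.array([-rim_dir[1], rim_dir[0]])
        if rim_normal[1] > 0:
            rim_normal = -rim_normal
        _add_segment(img, c, c + 0.12 * sep * rim_normal, width=1.5, amp=90.0)
        _add_blob(img, a, sx=2.5, sy=4.0, amp=90.0)

    img = gaussian_filter(img, sigma=1.0)
    if config.noise_sigma > 0:
        rng = np.random.default_rng(config.seed)
        img = img + rng.normal(0.0, config.noise_sigma, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

def sample_angles(rng: np.random.Generator, criteria: CategoryCriteria | None = None) -> tuple[float, float, float]:
    """Draw one hip's (ce, tonnis, sharp) triple.

    Per angle, a category is drawn (normal 0.5, borderline 0.25, DDH 0.25)
    and the value uniformly within that category's band, so all three
    categories of every angle appear in moderately sized datasets while
    normal anatomy remains the most common.
    """
    criteria = criteria or CategoryCriteria()
    bands = {
        "ce": ((25.0, 38.0), (20.0, 25.0), (8.0, 20.0)),
        "tonnis": ((0.0, 10.0), (10.0, 13.0), (13.0, 24.0)),
        "sharp": ((34.0, 42.0), (42.0, 47.0), (47.0, 56.0)),
    }
    out = []
    for name in ("ce", "tonnis", "sharp"):
        cat = rng.choice(3, p=[0.5, 0.25, 0.25])
        lo, hi = bands[name][cat]
        out.append(float(rng.uniform(lo, hi)))
    return tuple(out)  # type: ignore[return-value]


@dataclass
class PhantomDataset:
    """In-memory manifest of a generated phantom dataset."""

    images: list[np.ndarray]
    ground_truth: list[PelvisAnnotation]
    consensus: list[PelvisAnnotation]
    replicates: list[list[PelvisAnnotation]]  # [image][rater]
    angle_table: pd.DataFrame  # image_id, side, ce_deg, tonnis_deg, sharp_deg, label
    configs: list[PhantomConfig]

    def __len__(self) -> int:
        return len(self.images)


def _jittered(ann: PelvisAnnotation, rater: RaterModel, rng: np.random.Generator) -> PelvisAnnotation:
    kps = [
        Keypoint(
            k.x + rng.normal(0.0, rater.sigma(k.label)),
            k.y + rng.normal(0.0, rater.sigma(k.label)),
            k.label,
            k.side,
        )
        for k in ann.keypoints
    ]
    coords = np.array([[k.x, k.y] for k in kps])
    return PelvisAnnotation(kps, tight_bbox(coords), ann.image_id)


def _mean_annotation(replicates: Sequence[PelvisAnnotation]) -> PelvisAnnotation:
    coords = np.mean([r.coords() for r in replicates], axis=0)
    bbox = tuple(np.mean([r.bbox for r in replicates], axis=0))
    return PelvisAnnotation.from_coords(coords, bbox, replicates[0].image_id)


def generate_dataset(
    n_images: int,
    angle_sampler: Callable[[np.random.Generator], tuple[float, float, float]] | None = None,
    rater_model: RaterModel | None = None,
    seed: int = 0,
    *,
    image_size: int = 256,
    noise_sigma: float = 4.0,
    rotation_range_deg: float = 3.0,
    criteria: CategoryCriteria | None = None,
    scoring_params: ScoringParams | None = None,
) -> PhantomDataset:
    """Generate a reproducible phantom dataset.

    Per image, per-side angle triples are drawn from ``angle_sampler``
    (default :func:`sample_angles`), the landmarks constructed analytically,
    and the image rendered with a small random whole-pelvis rotation.  Each
    rater of ``rater_model`` re-labels the ground truth with Gaussian jitter;
    the consensus annotation is the replicate mean.  The diagnosis label per
    hip comes from the default scoring rule applied to the noiseless
    ground-truth angles.

    Raises if any angle category is unrepresented, unless
    ``n_images < SMALL_N_THRESHOLD`` in which case it warns and proceeds.
    """
    if n_images < 1:
        raise ValueError("n_images must be at least 1")
    sampler = angle_sampler or sample_angles
    rater_model = rater_model or RaterModel()
    criteria = criteria or CategoryCriteria()
    scoring_params = scoring_params or ScoringParams()
    rng = np.random.default_rng(seed)

    images, gts, consensuses, reps, configs, rows = [], [], [], [], [], []
    scale = image_size / 256.0
    for i in range(n_images):
        while True:
            right = sampler(rng)
            left = sampler(rng)
            cfg = PhantomConfig(
                image_height=image_size,
                image_width=image_size,
                ce_deg=(right[0], left[0]),
                tonnis_deg=(right[1], left[1]),
                sharp_deg=(right[2], left[2]),
                femoral_head_radius=20.0 * scale,
                teardrop_separation=110.0 * scale,
                noise_sigma=noise_sigma,
                rotation_deg=float(rng.uniform(-rotation_range_deg, rotation_range_deg)),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            try:
                gt = construct_landmarks(cfg)
                break
            except (PhantomGeometryError, ValueError):
                continue  # resample an out-of-bounds/contradictory triple
        gt = PelvisAnnotation(gt.keypoints, gt.bbox, image_id=f"{i:05d}")
        img = render_phantom(cfg, gt)
        replicates = [_jittered(gt, rater_model, rng) for _ in range(rater_model.n_raters)]
        consensus = _mean_annotation(replicates)

        for side, (ce, to, sh) in (("right", right), ("left", left)):
            diag = diagnose_from_angles(
                AngleMeasurements(side=side, ce_deg=ce, tonnis_deg=to, sharp_deg=sh),
                criteria,
                scoring_params,
            )
            rows.append(
                {
                    "image_id": gt.image_id,
                    "side": side,
                    "ce_deg": ce,
                    "tonnis_deg": to,
                    "sharp_deg": sh,
                    "label": int(diag.positive),
                }
            )
        images.append(img)
        gts.append(gt)
        consensuses.append(consensus)
        reps.append(replicates)
        configs.append(cfg)

    table = pd.DataFrame(rows)
    _check_category_coverage(table, criteria, n_images)
    return PhantomDataset(images, gts, consensuses, reps, table, configs)


def _check_category_coverage(table: pd.DataFrame, criteria: CategoryCriteria, n_images: int) -> None:
    from .scoring import categorize

    for name, col in (("ce", "ce_deg"), ("tonnis", "tonnis_deg"), ("sharp", "sharp_deg")):
        cats = {categorize(v, name, criteria) for v in table[col]}
        missing = {"normal", "borderline", "ddh"} - cats
        if missing:
            msg = f"angle {name}: categories {sorted(missing)} unrepresented in sampled dataset"
            if n_images < SMALL_N_THRESHOLD:
                warnings.warn(msg + f" (n_images={n_images} < {SMALL_N_THRESHOLD}; proceeding)")
            else:
                raise ValueError(msg)


# ---------------------------------------------------------------------------
# On-disk manifest
# ---------------------------------------------------------------------------

def save_dataset(ds: PhantomDataset, out_dir: str | Path) -> Path:
    """Write images (PNG), annotations (COCO JSON), and the angle table (CSV)."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    sizes, names = {}, {}
    for img, gt in zip(ds.images, ds.ground_truth):
        fname = f"{gt.image_id}.png"
        Image.fromarray(img).save(out / "images" / fname)
        sizes[gt.image_id] = img.shape
        names[gt.image_id] = fname
    write_coco_annotations(ds.ground_truth, out / "ground_truth.json", sizes, names)
    write_coco_annotations(ds.consensus, out / "annotations.json", sizes, names)
    rater_dir = out / "raters"
    rater_dir.mkdir(exist_ok=True)
    n_raters = len(ds.replicates[0]) if ds.replicates else 0
    for r in range(n_raters):
        write_coco_annotations(
            [reps[r] for reps in ds.replicates], rater_dir / f"rater_{r}.json", sizes, names
        )
    ds.angle_table.to_csv(out / "angles.csv", index=False)
    return out


def load_dataset(out_dir: str | Path) -> PhantomDataset:
    """Reload a saved manifest (configs are not persisted)."""
    out = Path(out_dir)
    gts = read_coco_annotations(out / "ground_truth.json")
    consensus = read_coco_annotations(out / "annotations.json")
    reps_by_rater = [
        read_coco_annotations(p) for p in sorted((out / "raters").glob("rater_*.json"))
    ]
    replicates = [
        [rater[i] for rater in reps_by_rater] for i in range(len(gts))
    ] if reps_by_rater else [[] for _ in gts]
    images = [
        np.asarray(Image.open(out / "images" / f"{gt.image_id}.png"))
        for gt in gts
    ]
    table = pd.read_csv(out / "angles.csv", dtype={"image_id": str})
    return PhantomDataset(images, gts, consensus, replicates, table, [])
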