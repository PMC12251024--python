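"""Region-based keypoint detection network for pelvic landmarks.

A compact convolutional detector, written on numpy primitives
(:mod:`hipmetrics._nn`), that follows the region-based keypoint design: a
convolutional backbone extracts a stride-4 feature map; a single-class
proposal head scores objectness per feature cell and regresses a pelvis
box from an anchor; RoIAlign pools the backbone features over the region
of interest; and two parallel branches process the pooled features — a
keypoint branch producing one probability map per landmark (per-pixel
sigmoid over a ``mask_resolution`` grid, supervised by "one-hot" masks in
which only the pixel at the keypoint location is 1) and a box-regression
branch refining the proposal.  There is no object-classification head
beyond the single-class objectness of the proposal stage.

Training minimizes ``L = L_kp + L_box`` (plus the proposal-stage objectness
term), where ``L_kp`` is the focal loss

    L_kp = -(1/N) sum_k sum_i sum_j  (1-p)^gamma log p      at y = 1
                                      p^gamma log(1-p)       at y = 0

with focusing parameter ``gamma`` (default 2) and ``N`` the number of
foreground pixels, and ``L_box`` is the Smooth-L1 loss summed over the four
box parameters (x, y, w, h).  Optimization is SGD (momentum 0.9, weight
decay 1e-4), initial learning rate 0.005, divided by 5 when the validation
loss plateaus for three consecutive epochs; default 15 epochs at mini-batch
size 4, with small-angle rotation and additive-noise augmentation.

Keypoint decoding takes, per channel, the argmax pixel of the probability
map (ties broken toward the lowest row, then column) and maps its cell
center back to image coordinates through the RoI transform.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage
from sklearn.model_selection import KFold

from ._nn import SGD, Conv2d, Linear, Param, ReLU, roi_align, roi_align_backward
from .geometry import KEYPOINT_ORDER, PelvisAnnotation

__all__ = [
    "BACKBONES",
    "DetectorConfig",
    "TrainConfig",
    "BoxParams",
    "make_keypoint_target",
    "focal_keypoint_loss",
    "smooth_l1_box_loss",
    "total_loss",
    "build_detector",
    "KeypointDetector",
    "augment",
    "train_detector",
    "decode_keypoints",
    "crossval_train",
    "save_detector",
    "load_detector",
]

#: Backbone variants for the sensitivity harness: channel widths of the four
#: convolutional stages (two stride-2, two stride-1, the last dilated).
BACKBONES = {
    "base": (12, 24, 32, 32),
    "wide": (16, 32, 48, 48),
    "deep": (12, 24, 32, 32, 32),
}

_FEATURE_STRIDE = 4
_OBJ_WEIGHT = 4.0  # balances the single-image objectness term against L_kp


@dataclass(frozen=True)
class DetectorConfig:
    """Architecture hyperparameters of the keypoint detector.

    ``mask_resolution`` is the side length of the per-keypoint probability
    grid over the RoI.  The default (112) keeps the grid cell below ~2 px
    for a pelvis RoI of ~220 px, so that argmax quantization contributes
    well under a degree to every measured angle (the Tönnis angle, with its
    short lever arm, is the binding constraint).  ``target_mask_kind``
    switches the supervision between the default one-hot binary masks and
    Gaussian heatmaps (sensitivity harness only).
    """

    backbone: str = "base"
    keypoint_count: int = 8
    mask_resolution: int = 112
    focal_gamma: float = 2.0
    target_mask_kind: str = "one-hot"
    input_size: int = 256
    focal_normalizer: str = "foreground"  # or "total"
    heatmap_sigma: float = 2.0  # grid cells, heatmap kind only

    def __post_init__(self) -> None:
        if self.backbone not in BACKBONES:
            raise ValueError(f"unknown backbone {self.backbone!r}; choose from {sorted(BACKBONES)}")
        if self.keypoint_count != 8:
            raise ValueError("the pelvis annotation scheme has exactly 8 keypoints")
        if self.mask_resolution < 14:
            raise ValueError("mask_resolution must be at least 14")
        if self.focal_gamma < 0:
            raise ValueError("focal_gamma must be non-negative")
        if self.target_mask_kind not in ("one-hot", "heatmap"):
            raise ValueError("target_mask_kind must be 'one-hot' or 'heatmap'")
        if self.focal_normalizer not in ("foreground", "total"):
            raise ValueError("focal_normalizer must be 'foreground' or 'total'")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization schedule: SGD with plateau-based learning-rate decay."""

    learning_rate: float = 0.005
    plateau_factor: float = 5.0
    plateau_patience: int = 3
    epochs: int = 15
    batch_size: int = 4
    momentum: float = 0.9
    weight_decay: float = 1e-4
    rotation_range_deg: float = 5.0
    noise_sigma: float = 2.0
    val_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.plateau_factor, self.epochs, self.batch_size) <= 0:
            raise ValueError("rates and sizes must be positive")


@dataclass(frozen=True)
class BoxParams:
    """Bounding-box parameters (x, y, w, h): top-left corner, width, height."""

    x: float
    y: float
    w: float
    h: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.w, self.h], dtype=float)

    @classmethod
    def from_any(cls, box) -> "BoxParams":
        if isinstance(box, BoxParams):
            return box
        x, y, w, h = (float(v) for v in box)
        return cls(x, y, w, h)


# ---------------------------------------------------------------------------
# Targets and losses
# ---------------------------------------------------------------------------

def make_keypoint_target(
    annotation: PelvisAnnotation, roi, config: DetectorConfig
) -> np.ndarray:
    """Per-keypoint supervision masks of shape (K, S, S) over the RoI grid.

    One-hot kind: each keypoint's image coordinates are mapped to the RoI
    grid with half-open pixel bins (floor to the containing cell) and that
    single pixel is set to 1.  Heatmap kind: a Gaussian with peak exactly at
    the keypoint's cell.  Raises if any keypoint falls outside the RoI.
    """
    roi = BoxParams.from_any(roi)
    s = config.mask_resolution
    target = np.zeros((config.keypoint_count, s, s), dtype=np.float32)
    for k, kp in enumerate(annotation.keypoints):
        u = (kp.x - roi.x) / roi.w * s
        v = (kp.y - roi.y) / roi.h * s
        if not (0 <= u < s and 0 <= v < s):
            raise ValueError(
                f"keypoint {kp.side}-{kp.label} at ({kp.x:.1f}, {kp.y:.1f}) "
                "falls outside the RoI; clip or discard the sample"
            )
        col, row = int(u), int(v)
        if config.target_mask_kind == "one-hot":
            target[k, row, col] = 1.0
        else:
            rr, cc = np.mgrid[0:s, 0:s]
            target[k] = np.exp(
                -((rr - row) ** 2 + (cc - col) ** 2) / (2.0 * config.heatmap_sigma**2)
            )
    return target


def focal_keypoint_loss(
    pred_probs: np.ndarray,
    target: np.ndarray,
    gamma: float = 2.0,
    normalizer: float | None = None,
) -> float:
    """Focal keypoint loss over (K, H, W) probability maps.

    Foreground pixels (y=1) contribute ``(1-p)^gamma log p``, background
    pixels ``p^gamma log(1-p)``; the sum is negated and divided by ``N``
    (default: the number of foreground pixels).  At ``gamma = 0`` this is
    exactly the summed binary cross-entropy.
    """
    p = np.asarray(pred_probs, dtype=np.float64)
    y = np.asarray(target, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: probs {p.shape} vs target {y.shape}")
    p = np.clip(p, 1e-12, 1 - 1e-12)
    fg = y == 1
    n = float(normalizer) if normalizer is not None else max(float(fg.sum()), 1.0)
    loss = -(
        np.sum((1 - p[fg]) ** gamma * np.log(p[fg]))
        + np.sum(p[~fg] ** gamma * np.log(1 - p[~fg]))
    )
    return float(loss / n)


def _focal_grad_logits(
    probs: np.ndarray, target: np.ndarray, gamma: float, n: float
) -> np.ndarray:
    """d(focal loss)/d(logits), for sigmoid-activated probability maps."""
    p = np.clip(probs.astype(np.float64), 1e-7, 1 - 1e-7)
    y = target
    fg = y == 1
    dldp = np.empty_like(p)
    # d/dp [-(1-p)^g log p] = g (1-p)^(g-1) log p - (1-p)^g / p
    dldp[fg] = gamma * (1 - p[fg]) ** max(gamma - 1, 0) * np.log(p[fg]) - (1 - p[fg]) ** gamma / p[fg]
    # d/dp [-p^g log(1-p)] = -g p^(g-1) log(1-p) + p^g / (1-p)
    dldp[~fg] = -gamma * p[~fg] ** max(gamma - 1, 0) * np.log(1 - p[~fg]) + p[~fg] ** gamma / (1 - p[~fg])
    return ((dldp * p * (1 - p)) / n).astype(np.float32)


def _smooth_l1(d: np.ndarray) -> np.ndarray:
    ad = np.abs(d)
    return np.where(ad < 1.0, 0.5 * d * d, ad - 0.5)


def _smooth_l1_grad(d: np.ndarray) -> np.ndarray:
    return np.clip(d, -1.0, 1.0)


def smooth_l1_box_loss(t_hat, t) -> float:
    """Smooth-L1 loss summed over the four box parameters (x, y, w, h).

    ``0.5 d^2`` for ``|d| < 1`` and ``|d| - 0.5`` otherwise, with
    ``d = t_i - t_hat_i``.  Operates on whatever parameter scale it is
    given: raw pixel boxes or proposal-relative normalized offsets.
    """
    a = BoxParams.from_any(t_hat).as_array()
    b = BoxParams.from_any(t).as_array()
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("box parameters must be finite")
    return float(np.sum(_smooth_l1(b - a)))


def total_loss(kp_loss: float, box_loss: float) -> float:
    """Unweighted sum of the keypoint and box losses."""
    if not (math.isfinite(kp_loss) and math.isfinite(box_loss)):
        raise ValueError("loss terms must be finite")
    return kp_loss + box_loss


# ---------------------------------------------------------------------------
# Box delta parameterization (proposal-relative normalized offsets)
# ---------------------------------------------------------------------------

def box_to_deltas(proposal: BoxParams, gt: BoxParams) -> np.ndarray:
    px, py = proposal.x + proposal.w / 2, proposal.y + proposal.h / 2
    gx, gy = gt.x + gt.w / 2, gt.y + gt.h / 2
    return np.array(
        [
            (gx - px) / proposal.w,
            (gy - py) / proposal.h,
            math.log(gt.w / proposal.w),
            math.log(gt.h / proposal.h),
        ],
        dtype=np.float32,
    )


def deltas_to_box(proposal: BoxParams, deltas: np.ndarray) -> BoxParams:
    px, py = proposal.x + proposal.w / 2, proposal.y + proposal.h / 2
    cx = px + float(deltas[0]) * proposal.w
    cy = py + float(deltas[1]) * proposal.h
    w = proposal.w * math.exp(float(np.clip(deltas[2], -2, 2)))
    h = proposal.h * math.exp(float(np.clip(deltas[3], -2, 2)))
    return BoxParams(cx - w / 2, cy - h / 2, w, h)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -30, 30)))


def _with_coords(pooled: np.ndarray) -> np.ndarray:
    """Append RoI-normalized coordinate channels (x, y in [-1, 1])."""
    _, sh, sw = pooled.shape
    ys = np.linspace(-1.0, 1.0, sh, dtype=np.float32)
    xs = np.linspace(-1.0, 1.0, sw, dtype=np.float32)
    yy = np.repeat(ys[:, None], sw, axis=1)[None]
    xx = np.repeat(xs[None, :], sh, axis=0)[None]
    return np.concatenate([pooled, xx, yy], axis=0)


# ---------------------------------------------------------------------------
# The detector
# ---------------------------------------------------------------------------

class KeypointDetector:
    """Backbone + proposal stage + RoIAlign + keypoint/box branches."""

    def __init__(self, config: DetectorConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        widths = BACKBONES[config.backbone]
        self.backbone: list = []
        c_in = 1
        for i, c_out in enumerate(widths):
            stride = 2 if i < 2 else 1
            dilation = 4 if i == len(widths) - 1 else 1
            self.backbone.append(Conv2d(c_in, c_out, 3, stride=stride, dilation=dilation, rng=rng))
            self.backbone.append(ReLU())
            c_in = c_out
        c_feat = c_in
        self.rpn_hidden = Conv2d(c_feat, 16, 3, rng=rng)
        self.rpn_relu = ReLU()
        self.rpn_out = Conv2d(16, 5, 1, rng=rng, bias_init=0.0)
        s = config.mask_resolution
        # pooled features are augmented with 2 RoI-normalized coordinate
        # channels (CoordConv): landmark layout within the pelvis RoI is
        # highly stereotyped, and explicit coordinates let the branches use
        # that prior from the first epochs
        self.kp_conv1 = Conv2d(c_feat + 2, 24, 3, rng=rng)
        self.kp_relu = ReLU()
        # background-prior bias initialization keeps early background loss small
        self.kp_conv2 = Conv2d(24, config.keypoint_count, 3, rng=rng, bias_init=-math.log((1 - 1e-3) / 1e-3))
        self.box_pool = 7
        self.box_fc1 = Linear((c_feat + 2) * self.box_pool**2, 64, rng=rng)
        self.box_relu = ReLU()
        self.box_fc2 = Linear(64, 4, rng=rng)
        self._anchor = BoxParams(
            config.input_size * 0.1,
            config.input_size * 0.25,
            config.input_size * 0.8,
            config.input_size * 0.5,
        )

    # -- parameters ---------------------------------------------------------
    @property
    def params(self) -> list[Param]:
        layers = self.backbone + [
            self.rpn_hidden, self.rpn_out, self.kp_conv1, self.kp_conv2,
            self.box_fc1, self.box_fc2,
        ]
        out: list[Param] = []
        for layer in layers:
            out.extend(getattr(layer, "params", []))
        return out

    # -- forward pieces ------------------------------------------------------
    @staticmethod
    def _normalize(image: np.ndarray) -> np.ndarray:
        return ((image.astype(np.float32) / 255.0 - 0.5) * 2.0)[None]

    def _backbone_forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.backbone:
            x = layer.forward(x)
        return x

    def _backbone_backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.backbone):
            dout = layer.backward(dout)

    def _rpn_forward(self, feat: np.ndarray) -> np.ndarray:
        return self.rpn_out.forward(self.rpn_relu.forward(self.rpn_hidden.forward(feat)))

    def _rpn_backward(self, dout: np.ndarray) -> np.ndarray:
        return self.rpn_hidden.backward(self.rpn_relu.backward(self.rpn_out.backward(dout)))

    def _kp_forward(self, pooled: np.ndarray) -> np.ndarray:
        return self.kp_conv2.forward(self.kp_relu.forward(self.kp_conv1.forward(_with_coords(pooled))))

    def _kp_backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.kp_conv1.backward(self.kp_relu.backward(self.kp_conv2.backward(dout)))
        return d[:-2]  # drop the coordinate channels

    def _box_forward(self, pooled: np.ndarray) -> np.ndarray:
        return self.box_fc2.forward(
            self.box_relu.forward(self.box_fc1.forward(_with_coords(pooled).ravel()))
        )

    def _box_backward(self, dout: np.ndarray, pooled_shape) -> np.ndarray:
        d = self.box_fc1.backward(self.box_relu.backward(self.box_fc2.backward(dout)))
        c, sh, sw = pooled_shape
        return d.reshape(c + 2, sh, sw)[:-2]

    # -- inference -----------------------------------------------------------
    def forward(self, image: np.ndarray, roi=None) -> dict:
        """Run the full network on one image.

        When ``roi`` is None the highest-objectness proposal, refined by the
        box branch, defines the region of interest.  Returns keypoint
        probability maps, the refined box, and the objectness map.
        """
        feat = self._backbone_forward(self._normalize(image))
        rpn = self._rpn_forward(feat)
        obj = _sigmoid(rpn[0])
        if roi is None:
            # decode the proposals of the highest-objectness cells and take
            # their objectness-weighted mean box: far more stable than a
            # single argmax cell on a near-uniform objectness plateau
            flat = obj.ravel()
            top = np.argsort(flat)[-9:]
            boxes, weights = [], []
            for idx in top:
                ci, cj = np.unravel_index(int(idx), obj.shape)
                boxes.append(deltas_to_box(self._cell_anchor(ci, cj), rpn[1:5, ci, cj]).as_array())
                weights.append(flat[idx])
            w = np.asarray(weights) / max(float(np.sum(weights)), 1e-9)
            proposal = BoxParams.from_any(np.sum(np.asarray(boxes) * w[:, None], axis=0))
            roi_box = self._clip_box(proposal, image.shape)
            # two refinement passes of the box branch (cascade refinement)
            for _ in range(2):
                pooled_bx, _ = roi_align(
                    feat, roi_box.as_array(), (self.box_pool, self.box_pool), _FEATURE_STRIDE
                )
                refined = deltas_to_box(roi_box, self._box_forward(pooled_bx))
                roi_box = self._clip_box(refined, image.shape)
            # fixed context margin: landmark decoding needs the RoI to
            # contain all 8 keypoints, so trade a little grid resolution
            # for containment robustness
            roi_box = self._clip_box(
                BoxParams(
                    roi_box.x - 0.06 * roi_box.w,
                    roi_box.y - 0.06 * roi_box.h,
                    1.12 * roi_box.w,
                    1.12 * roi_box.h,
                ),
                image.shape,
            )
        else:
            roi_box = BoxParams.from_any(roi)
        s = self.config.mask_resolution
        pooled_kp, _ = roi_align(feat, roi_box.as_array(), (s, s), _FEATURE_STRIDE)
        probs = _sigmoid(self._kp_forward(pooled_kp))
        return {"keypoint_probs": probs, "roi": roi_box, "objectness": obj}

    def _cell_anchor(self, ci: int, cj: int) -> BoxParams:
        """The single anchor at feature cell (row ci, col cj)."""
        return BoxParams(
            (cj + 0.5) * _FEATURE_STRIDE - self._anchor.w / 2,
            (ci + 0.5) * _FEATURE_STRIDE - self._anchor.h / 2,
            self._anchor.w,
            self._anchor.h,
        )

    @staticmethod
    def _clip_box(box: BoxParams, shape) -> BoxParams:
        h, w = shape[:2]
        x0 = float(np.clip(box.x, 0, w - 8))
        y0 = float(np.clip(box.y, 0, h - 8))
        x1 = float(np.clip(box.x + box.w, x0 + 8, w))
        y1 = float(np.clip(box.y + box.h, y0 + 8, h))
        return BoxParams(x0, y0, x1 - x0, y1 - y0)

    def predict(self, image: np.ndarray) -> PelvisAnnotation:
        """Detect the pelvis RoI and decode the 8 keypoints on one image."""
        out = self.forward(image)
        return decode_keypoints(out["keypoint_probs"], out["roi"])

    # -- one training example ------------------------------------------------
    def train_step(
        self,
        image: np.ndarray,
        annotation: PelvisAnnotation,
        rng: np.random.Generator | None = None,
        backward: bool = True,
    ) -> dict:
        """Forward and (optionally) backward pass on one image.

        Gradients are accumulated into the parameters; the caller owns
        optimizer stepping and gradient zeroing.  Returns the loss terms.
        """
        cfg = self.config
        gt_box = BoxParams.from_any(annotation.bbox)
        gt_box = self._clip_box(gt_box, image.shape)
        feat = self._backbone_forward(self._normalize(image))
        dfeat = np.zeros_like(feat)

        # --- proposal stage: objectness + anchor deltas ---
        rpn = self._rpn_forward(feat)
        obj_logits = rpn[0]
        hf, wf = obj_logits.shape
        # region labels with an ignore band: cells whose center falls in the
        # central half of the pelvis box are positive, the rest of the box
        # interior is ignored (locally indistinguishable), everything else is
        # negative
        cell_x = (np.arange(wf) + 0.5) * _FEATURE_STRIDE
        cell_y = (np.arange(hf) + 0.5) * _FEATURE_STRIDE
        in_x = (cell_x >= gt_box.x) & (cell_x < gt_box.x + gt_box.w)
        in_y = (cell_y >= gt_box.y) & (cell_y < gt_box.y + gt_box.h)
        core_x = (cell_x >= gt_box.x + 0.25 * gt_box.w) & (cell_x < gt_box.x + 0.75 * gt_box.w)
        core_y = (cell_y >= gt_box.y + 0.25 * gt_box.h) & (cell_y < gt_box.y + 0.75 * gt_box.h)
        inside = in_y[:, None] & in_x[None, :]
        pos = core_y[:, None] & core_x[None, :]
        neg = ~inside
        n_pos = max(float(pos.sum()), 1.0)
        n_neg = max(float(neg.sum()), 1.0)
        w_map = (pos * (0.5 / n_pos) + neg * (0.5 / n_neg)).astype(np.float32)
        obj_t = pos.astype(np.float32)
        p_obj = _sigmoid(obj_logits)
        eps = 1e-7
        rpn_obj_loss = -_OBJ_WEIGHT * float(
            np.sum(w_map * (obj_t * np.log(p_obj + eps) + (1 - obj_t) * np.log(1 - p_obj + eps)))
        )
        # anchor deltas at every positive cell, each against its own anchor
        pys, pxs = np.nonzero(pos)
        t_rpn = np.stack(
            [
                box_to_deltas(self._cell_anchor(ci, cj), gt_box)
                for ci, cj in zip(pys, pxs)
            ],
            axis=1,
        )  # (4, n_pos)
        d_rpn = rpn[1:5, pys, pxs] - t_rpn
        rpn_box_loss = float(np.mean(np.sum(_smooth_l1(d_rpn), axis=0)))

        # --- proposal for the branches: jittered GT box (train-time) ---
        if rng is not None:
            jit = rng.uniform(-0.10, 0.10, size=4)
            prop = BoxParams(
                gt_box.x + jit[0] * gt_box.w,
                gt_box.y + jit[1] * gt_box.h,
                gt_box.w * (1 + jit[2]),
                gt_box.h * (1 + jit[3]),
            )
            prop = self._clip_box(prop, image.shape)
            # grow the proposal if the jitter pushed any keypoint outside:
            # the keypoint branch must always see all 8 landmarks
            coords = annotation.coords()
            margin_x, margin_y = 0.02 * prop.w, 0.02 * prop.h
            x0 = min(prop.x, coords[:, 0].min() - margin_x)
            y0 = min(prop.y, coords[:, 1].min() - margin_y)
            x1 = max(prop.x + prop.w, coords[:, 0].max() + margin_x)
            y1 = max(prop.y + prop.h, coords[:, 1].max() + margin_y)
            prop = BoxParams(x0, y0, x1 - x0, y1 - y0)
        else:
            prop = gt_box

        # --- keypoint branch ---
        s = cfg.mask_resolution
        pooled_kp, cache_kp = roi_align(feat, prop.as_array(), (s, s), _FEATURE_STRIDE)
        logits = self._kp_forward(pooled_kp)
        probs = _sigmoid(logits)
        target = make_keypoint_target(annotation, prop, cfg)
        if cfg.focal_normalizer == "foreground":
            n_norm = max(float((target == 1).sum()), 1.0)
        else:
            n_norm = float(target.size)
        kp_loss = focal_keypoint_loss(probs, target, cfg.focal_gamma, n_norm)

        # --- box branch ---
        pooled_bx, cache_bx = roi_align(feat, prop.as_array(), (self.box_pool, self.box_pool), _FEATURE_STRIDE)
        deltas = self._box_forward(pooled_bx)
        t_star = box_to_deltas(prop, gt_box)
        d_box = deltas - t_star
        box_loss = float(np.sum(_smooth_l1(d_box)))

        losses = {
            "kp": kp_loss,
            "box": box_loss,
            "rpn_obj": rpn_obj_loss,
            "rpn_box": rpn_box_loss,
        }
        losses["total"] = total_loss(kp_loss, box_loss) + rpn_obj_loss + rpn_box_loss
        if not math.isfinite(losses["total"]):
            raise FloatingPointError(f"non-finite training loss: {losses}")
        if not backward:
            return losses

        # --- backward ---
        dlogits = _focal_grad_logits(probs, target, cfg.focal_gamma, n_norm)
        dfeat += roi_align_backward(self._kp_backward(dlogits), cache_kp)
        ddeltas = _smooth_l1_grad(d_box)
        dfeat += roi_align_backward(self._box_backward(ddeltas, pooled_bx.shape), cache_bx)
        drpn = np.zeros_like(rpn)
        drpn[0] = _OBJ_WEIGHT * w_map * (p_obj - obj_t)
        drpn[1:5, pys, pxs] = _smooth_l1_grad(d_rpn) / len(pys)
        dfeat += self._rpn_backward(drpn)
        self._backbone_backward(dfeat)
        return losses


def build_detector(config: DetectorConfig | None = None, seed: int = 0) -> KeypointDetector:
    """Instantiate a detector for a configuration (raises on unknown backbone)."""
    return KeypointDetector(config or DetectorConfig(), seed=seed)


# ---------------------------------------------------------------------------
# Decoding
# ---------------------------------------------------------------------------

def decode_keypoints(pred_probs: np.ndarray, roi) -> PelvisAnnotation:
    """Per-channel argmax decoding of keypoint probability maps.

    Ties break toward the lowest row, then the lowest column (row-major
    first occurrence).  The winning cell's center is mapped back to image
    coordinates through the RoI transform; keypoints are assembled in
    canonical order with the RoI as the annotation's box.
    """
    probs = np.asarray(pred_probs)
    if not np.all(np.isfinite(probs)):
        raise ValueError("non-finite keypoint probability maps")
    roi = BoxParams.from_any(roi)
    k, sh, sw = probs.shape
    coords = np.empty((k, 2))
    for ch in range(k):
        idx = int(np.argmax(probs[ch]))
        row, col = divmod(idx, sw)
        coords[ch, 0] = roi.x + (col + 0.5) * roi.w / sw
        coords[ch, 1] = roi.y + (row + 0.5) * roi.h / sh
    return PelvisAnnotation.from_coords(coords, (roi.x, roi.y, roi.w, roi.h), image_id="pred")


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

def augment(
    image: np.ndarray,
    annotation: PelvisAnnotation,
    rng: np.random.Generator,
    rotation_range_deg: float = 5.0,
    noise_sigma: float = 2.0,
    max_tries: int = 10,
) -> tuple[np.ndarray, PelvisAnnotation]:
    """Jointly rotate image and annotation by a small random angle; add noise.

    Rotation is about the image center; a draw that would push any keypoint
    out of bounds is rejected and redrawn (up to ``max_tries``, then the
    identity rotation is used).  Keypoints stay consistent with the rotated
    image content, so angles measured from the augmented annotation equal
    the originals.
    """
    h, w = image.shape
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    for _ in range(max_tries):
        angle = float(rng.uniform(-rotation_range_deg, rotation_range_deg))
        th = math.radians(angle)
        # scipy.ndimage.rotate(angle) maps input point p to c + R(-th_rows) (p - c)
        # in (row, col); in (x, y) raster coordinates this is a rotation by -th.
        rot = np.array([[math.cos(th), math.sin(th)], [-math.sin(th), math.cos(th)]])
        new_ann = annotation.transformed(lambda pts: (pts - center) @ rot.T + center)
        cs = new_ann.coords()
        if cs[:, 0].min() >= 1 and cs[:, 1].min() >= 1 and cs[:, 0].max() < w - 1 and cs[:, 1].max() < h - 1:
            break
    else:
        angle, new_ann = 0.0, annotation
    out = ndimage.rotate(
        image.astype(np.float32), angle, reshape=False, order=1, mode="nearest"
    )
    if noise_sigma > 0:
        out = out + rng.normal(0.0, noise_sigma, size=out.shape)
    return np.clip(out, 0, 255).astype(image.dtype), new_ann


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def train_detector(
    dataset,
    train_config: TrainConfig | None = None,
    config: DetectorConfig | None = None,
    *,
    train_indices: Sequence[int] | None = None,
    val_indices: Sequence[int] | None = None,
    model: KeypointDetector | None = None,
    progress: bool = False,
) -> tuple[KeypointDetector, dict]:
    """Train a detector on a phantom dataset manifest.

    ``dataset`` needs ``images`` and ``consensus`` attributes (a
    :class:`~hipmetrics.phantom.PhantomDataset`).  Without explicit index
    lists, a seeded shuffle holds out ``val_fraction`` of images for the
    plateau scheduler.  Returns the model and a per-epoch history of train
    loss, validation loss, and learning rate.
    """
    tc = train_config or TrainConfig()
    dc = config or DetectorConfig()
    rng = np.random.default_rng(tc.seed)
    n = len(dataset.images)
    if train_indices is None or val_indices is None:
        order = rng.permutation(n)
        n_val = max(1, int(round(tc.val_fraction * n)))
        val_indices = order[:n_val].tolist()
        train_indices = order[n_val:].tolist()
    if len(train_indices) == 0 or len(val_indices) == 0:
        raise ValueError("both train and validation splits must be non-empty")

    model = model or build_detector(dc, seed=tc.seed)
    opt = SGD(model.params, lr=tc.learning_rate, momentum=tc.momentum, weight_decay=tc.weight_decay)
    history = {"train_loss": [], "val_loss": [], "lr": [], "kp_loss": [], "box_loss": []}
    best_val = math.inf
    plateau = 0
    anns = dataset.consensus
    for epoch in range(tc.epochs):
        idx = np.array(train_indices)
        rng.shuffle(idx)
        losses, kp_losses, box_losses = [], [], []
        for start in range(0, len(idx), tc.batch_size):
            batch = idx[start : start + tc.batch_size]
            opt.zero_grad()
            for i in batch:
                img, ann = augment(
                    dataset.images[i], anns[i], rng, tc.rotation_range_deg, tc.noise_sigma
                )
                terms = model.train_step(img, ann, rng=rng)
                losses.append(terms["total"])
                kp_losses.append(terms["kp"])
                box_losses.append(terms["box"])
            for p in model.params:
                p.grad /= len(batch)
            opt.clip_grad_norm(10.0)
            opt.step()
        val = float(
            np.mean(
                [
                    model.train_step(dataset.images[i], anns[i], rng=None, backward=False)["total"]
                    for i in val_indices
                ]
            )
        )
        history["train_loss"].append(float(np.mean(losses)))
        history["kp_loss"].append(float(np.mean(kp_losses)))
        history["box_loss"].append(float(np.mean(box_losses)))
        history["val_loss"].append(val)
        history["lr"].append(opt.lr)
        if progress:
            print(
                f"epoch {epoch + 1}/{tc.epochs} train {history['train_loss'][-1]:.4f} "
                f"val {val:.4f} lr {opt.lr:g}"
            )
        if val < best_val - 1e-6:
            best_val = val
            plateau = 0
        else:
            plateau += 1
            if plateau >= tc.plateau_patience:
                opt.lr /= tc.plateau_factor
                plateau = 0
    return model, history


def crossval_train(
    dataset,
    k: int = 10,
    train_config: TrainConfig | None = None,
    config: DetectorConfig | None = None,
    progress: bool = False,
) -> tuple[list[KeypointDetector], list[np.ndarray]]:
    """k-fold cross-validated training: one model per fold.

    Fold splits are deterministic per seed; each model trains on k-1 folds
    with its held-out fold driving the plateau scheduler.  Returns the
    models and the validation-fold index arrays.
    """
    tc = train_config or TrainConfig()
    if k < 2:
        raise ValueError("k must be at least 2")
    n = len(dataset.images)
    if n < k:
        raise ValueError(f"dataset of {n} images cannot be split into {k} folds")
    kf = KFold(n_splits=k, shuffle=True, random_state=tc.seed)
    models, folds = [], []
    for fold, (tr, val) in enumerate(kf.split(np.arange(n))):
        fold_tc = replace(tc, seed=tc.seed + fold)
        m, _ = train_detector(
            dataset, fold_tc, config,
            train_indices=tr.tolist(), val_indices=val.tolist(), progress=progress,
        )
        models.append(m)
        folds.append(val)
    return models, folds


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_detector(model: KeypointDetector, path: str | Path) -> None:
    """Save weights as .npz with a JSON sidecar of the configuration."""
    path = Path(path)
    np.savez_compressed(path, **{f"p{i}": p.value for i, p in enumerate(model.params)})
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(asdict(model.config), indent=1))


def load_detector(path: str | Path) -> KeypointDetector:
    path = Path(path)
    cfg = DetectorConfig(**json.loads(path.with_suffix(".json").read_text()))
    model = build_detector(cfg)
    data = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
    for i, p in enumerate(model.params):
        p.value[...] = data[f"p{i}"]
    return model
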