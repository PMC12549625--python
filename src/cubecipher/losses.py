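"""Framework-free reference implementations of the training losses.

Pure NumPy forward functions for temperature-softened knowledge
distillation (softmax at temperature T, KL divergence, T^2-scaled
distillation loss), Focal Loss for class-imbalanced classification, IoU and
Complete-IoU (CIoU) bounding-box regression in center-size (x, y, w, h)
convention, the detection/total loss combinations, the OneCycleLR schedule,
and patience-based early stopping.  Natural logarithms throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .exceptions import ValidationError


@dataclass(frozen=True)
class BoxXYWH:
    """Axis-aligned box as center (x, y) and positive extents (w, h)."""

    x: float
    y: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValidationError(f"box extents must be positive, got w={self.w}, h={self.h}")

    @property
    def corners(self) -> tuple[float, float, float, float]:
        return (
            self.x - self.w / 2,
            self.y - self.h / 2,
            self.x + self.w / 2,
            self.y + self.h / 2,
        )

    @property
    def area(self) -> float:
        return self.w * self.h


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the distillation-augmented detector training.

    temperature softens teacher/student logits; alpha_distill weights the
    distillation term in the total loss; alpha_focal/gamma_focal shape the
    Focal Loss; lr_max/t_up/t_down parameterize the OneCycleLR ramp; training
    stops after ``patience`` epochs without validation improvement.
    """

    temperature: float = 4.0
    alpha_distill: float = 0.7
    alpha_focal: float = 0.25
    gamma_focal: float = 2.0
    lr_max: float = 1e-3
    t_up: float = 10.0
    t_down: float = 90.0
    patience: int = 10

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValidationError("temperature must be > 0")
        if not 0.0 <= self.alpha_distill <= 1.0:
            raise ValidationError("alpha_distill must lie in [0, 1]")
        if self.gamma_focal < 0:
            raise ValidationError("gamma_focal must be >= 0")
        if self.patience < 1:
            raise ValidationError("patience must be >= 1")


# ---------------------------------------------------------------------------
# distillation
# ---------------------------------------------------------------------------

def softened_probs(z, temperature: float) -> np.ndarray:
    """softmax(z / T), numerically stabilized by max subtraction."""
    if temperature <= 0:
        raise ValidationError(f"temperature={temperature!r} must be > 0")
    zz = np.asarray(z, dtype=np.float64)
    if zz.ndim != 1 or zz.size < 2:
        raise ValidationError("logits must be a 1-D vector of length >= 2")
    if not np.all(np.isfinite(zz)):
        raise ValidationError("logits must be finite")
    s = zz / temperature
    s -= s.max()
    e = np.exp(s)
    return e / e.sum()


def kl_divergence(pt, ps) -> float:
    """KL(pt || ps) = sum_i pt_i ln(pt_i / ps_i), natural log; >= 0."""
    p = np.asarray(pt, dtype=np.float64)
    q = np.asarray(ps, dtype=np.float64)
    if p.shape != q.shape:
        raise ValidationError(f"length mismatch: {p.shape} vs {q.shape}")
    if np.any(q <= 0.0):
        raise ValidationError("ps must be strictly positive")
    if np.any(p < 0.0):
        raise ValidationError("pt must be non-negative")
    mask = p > 0.0
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def distillation_loss(zt, zs, temperature: float) -> float:
    """T^2 * KL(softmax(zt/T) || softmax(zs/T)).

    The T^2 factor offsets the 1/T^2 gradient scaling introduced by the
    temperature softening.
    """
    return temperature**2 * kl_divergence(
        softened_probs(zt, temperature), softened_probs(zs, temperature)
    )


# ---------------------------------------------------------------------------
# focal loss
# ---------------------------------------------------------------------------

def p_t(p: float, y: int) -> float:
    """p if y == 1 else 1 - p, for p strictly inside (0, 1)."""
    if not 0.0 < p < 1.0:
        raise ValidationError(f"p={p!r} must lie in (0, 1)")
    if y not in (0, 1):
        raise ValidationError(f"label y={y!r} must be 0 or 1")
    return p if y == 1 else 1.0 - p


def focal_loss(p, y, alpha: float = 0.25, gamma: float = 2.0) -> float:
    """-alpha (1 - p_t)^gamma ln(p_t); arrays are reduced by the batch mean.

    With gamma=0 and alpha=1 this is exactly the binary cross-entropy.
    """
    pa = np.atleast_1d(np.asarray(p, dtype=np.float64))
    ya = np.atleast_1d(np.asarray(y))
    if pa.shape != ya.shape:
        raise ValidationError(f"shape mismatch: p {pa.shape} vs y {ya.shape}")
    if np.any((pa <= 0.0) | (pa >= 1.0)):
        raise ValidationError("all probabilities must lie strictly in (0, 1)")
    if not np.all(np.isin(ya, (0, 1))):
        raise ValidationError("labels must be 0 or 1")
    if gamma < 0:
        raise ValidationError(f"gamma={gamma!r} must be >= 0")
    pt = np.where(ya == 1, pa, 1.0 - pa)
    return float(np.mean(-alpha * (1.0 - pt) ** gamma * np.log(pt)))


# ---------------------------------------------------------------------------
# IoU / CIoU
# ---------------------------------------------------------------------------

def iou(b: BoxXYWH, bg: BoxXYWH) -> float:
    """Intersection-over-union of two center-size boxes, in [0, 1]."""
    ax1, ay1, ax2, ay2 = b.corners
    bx1, by1, bx2, by2 = bg.corners
    iw = max(0.0, min(ax2, bx2) - max(ax1, bx1))
    ih = max(0.0, min(ay2, by2) - max(ay1, by1))
    inter = iw * ih
    union = b.area + bg.area - inter
    return inter / union


class CIoUComponents(NamedTuple):
    """The intermediate terms of the CIoU loss, exposed for inspection."""

    iou: float
    center_distance_sq: float  # rho^2: squared center distance
    enclosing_diag_sq: float  # c^2: squared diagonal of the smallest enclosing box
    aspect_term: float  # v: (4 / pi^2) (arctan wg/hg - arctan w/h)^2
    tradeoff: float  # alpha = v / ((1 - IoU) + v)


def ciou_components(b: BoxXYWH, bg: BoxXYWH) -> CIoUComponents:
    """IoU, center-distance penalty, enclosing diagonal, aspect term, alpha."""
    overlap = iou(b, bg)
    rho2 = (b.x - bg.x) ** 2 + (b.y - bg.y) ** 2
    ax1, ay1, ax2, ay2 = b.corners
    bx1, by1, bx2, by2 = bg.corners
    cw = max(ax2, bx2) - min(ax1, bx1)
    ch = max(ay2, by2) - min(ay1, by1)
    c2 = cw * cw + ch * ch
    v = (4.0 / math.pi**2) * (math.atan(bg.w / bg.h) - math.atan(b.w / b.h)) ** 2
    denom = (1.0 - overlap) + v
    alpha = 0.0 if denom == 0.0 else v / denom
    return CIoUComponents(overlap, rho2, c2, v, alpha)


def ciou_loss(b: BoxXYWH, bg: BoxXYWH) -> float:
    """Complete-IoU loss: 1 - IoU + rho^2 / c^2 + alpha * v."""
    t = ciou_components(b, bg)
    return (1.0 - t.iou) + t.center_distance_sq / t.enclosing_diag_sq + t.tradeoff * t.aspect_term


# ---------------------------------------------------------------------------
# combination, schedule, stopping
# ---------------------------------------------------------------------------

def detection_loss(focal: float, ciou: float) -> float:
    """Detection loss = Focal Loss + CIoU Loss."""
    return focal + ciou


def total_loss(det: float, distill: float, alpha_distill: float) -> float:
    """(1 - alpha) * detection + alpha * distillation."""
    if not 0.0 <= alpha_distill <= 1.0:
        raise ValidationError(f"alpha_distill={alpha_distill!r} must lie in [0, 1]")
    return (1.0 - alpha_distill) * det + alpha_distill * distill


def onecycle_lr(t: float, lr_max: float, t_up: float, t_down: float) -> float:
    """OneCycleLR: linear ramp to lr_max over t_up, linear decay over t_down."""
    if t_up <= 0 or t_down <= 0:
        raise ValidationError("t_up and t_down must be > 0")
    if t < 0 or t > t_up + t_down:
        raise ValidationError(f"t={t!r} outside the cycle [0, {t_up + t_down}]")
    if t <= t_up:
        return lr_max * (t / t_up)
    return lr_max * (1.0 - (t - t_up) / t_down)


def early_stop(no_improve_count: int, patience: int = 10) -> bool:
    """True exactly when the stagnation counter has reached the patience."""
    if no_improve_count < 0:
        raise ValidationError("no_improve_count must be >= 0")
    if patience < 1:
        raise ValidationError("patience must be >= 1")
    return no_improve_count >= patience
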