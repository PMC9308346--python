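"""Multi-task detection loss: cross-entropy classification plus smooth-L1 or
balanced-L1 box regression, with the Faster R-CNN box-delta parameterization.

The balanced-L1 kernel reshapes smooth-L1 so that inlier residuals (|x| < 1)
contribute a larger gradient, while the outlier slope is capped at ``gamma``:

    balanced_l1(x) = (a/b)(b|x|+1) ln(b|x|+1) - a|x|      for |x| < 1
                     gamma |x| + C                         otherwise

with ``b`` solving ``a ln(b+1) = gamma`` (derivative continuity at |x| = 1)
and ``C`` chosen for value continuity there.  For the defaults a = 0.5,
gamma = 1.5 this gives b = e^3 - 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn.layers import softmax_cross_entropy


@dataclass(frozen=True)
class LossParams:
    """Parameters of the multi-task loss.

    ``lam`` balances classification against regression; ``alpha`` controls
    the inlier-gradient amplification and ``gamma`` the outlier slope of the
    balanced kernel.  ``b`` and ``c`` are derived, not free.
    """

    lam: float = 1.0
    alpha: float = 0.5
    gamma: float = 1.5
    kernel: str = "balanced"  # or "smooth"
    b: float = field(init=False)
    c: float = field(init=False)

    def __post_init__(self):
        if self.kernel not in ("balanced", "smooth"):
            raise ValueError(f"unknown regression kernel {self.kernel!r}")
        b, c = derive_balanced_constants(self.alpha, self.gamma)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "c", c)


def derive_balanced_constants(alpha: float, gamma: float) -> tuple[float, float]:
    """Solve for (b, C) from (alpha, gamma).

    Derivative continuity of the two branches at |x| = 1 requires
    ``alpha * ln(b + 1) = gamma``, hence ``b = exp(gamma/alpha) - 1``;
    value continuity then fixes
    ``C = (alpha/b)(b+1) ln(b+1) - alpha - gamma``.
    """
    if alpha <= 0 or gamma <= 0:
        raise ValueError(f"alpha and gamma must be positive, got {alpha}, {gamma}")
    b = np.expm1(gamma / alpha)
    c = (alpha / b) * (b + 1.0) * np.log(b + 1.0) - alpha - gamma
    return float(b), float(c)


def smooth_l1(x) -> np.ndarray:
    """0.5 x^2 for |x| < 1, |x| - 0.5 otherwise (elementwise)."""
    ax = np.abs(np.asarray(x, dtype=float))
    return np.where(ax < 1.0, 0.5 * ax * ax, ax - 0.5)


def smooth_l1_grad(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return np.clip(x, -1.0, 1.0)


def balanced_l1(x, params: LossParams | None = None) -> np.ndarray:
    """Balanced-L1 kernel (elementwise); even, C1, zero only at x = 0."""
    p = params or LossParams()
    ax = np.abs(np.asarray(x, dtype=float))
    a, b, g, c = p.alpha, p.b, p.gamma, p.c
    inner = (a / b) * (b * ax + 1.0) * np.log(b * ax + 1.0) - a * ax
    outer = g * ax + c
    return np.where(ax < 1.0, inner, outer)


def balanced_l1_grad(x, params: LossParams | None = None) -> np.ndarray:
    """d/dx balanced_l1: sign(x) * (alpha ln(b|x|+1)) inside, gamma outside."""
    p = params or LossParams()
    x = np.asarray(x, dtype=float)
    ax = np.abs(x)
    inner = p.alpha * np.log(p.b * ax + 1.0)
    return np.sign(x) * np.where(ax < 1.0, inner, p.gamma)


def regression_kernel(params: LossParams):
    """(value, grad) function pair selected by ``params.kernel``."""
    if params.kernel == "smooth":
        return smooth_l1, smooth_l1_grad
    return (lambda x: balanced_l1(x, params),
            lambda x: balanced_l1_grad(x, params))


# --------------------------------------------------------------------------
# loss terms
# --------------------------------------------------------------------------

def classification_loss(scores: np.ndarray, labels: np.ndarray,
                        n_cls: float | None = None):
    """Cross-entropy over class scores, normalized by ``n_cls`` (default:
    the number of samples).  Returns (loss, dscores)."""
    return softmax_cross_entropy(scores, labels, normalizer=n_cls)


def regression_loss(pred: np.ndarray, target: np.ndarray,
                    positive_mask: np.ndarray, n_reg: float,
                    params: LossParams):
    """Kernel loss over the (x, y, w, h) deltas of positive samples only.

    Returns (loss, dpred); negatives contribute neither value nor gradient,
    and the loss is exactly zero when no sample is positive.
    """
    pred = np.asarray(pred, dtype=float).reshape(-1, 4)
    target = np.asarray(target, dtype=float).reshape(-1, 4)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {target.shape}")
    mask = np.asarray(positive_mask, dtype=bool).reshape(-1)
    value_fn, grad_fn = regression_kernel(params)
    dpred = np.zeros_like(pred)
    if not mask.any():
        return 0.0, dpred
    residual = pred[mask] - target[mask]
    loss = value_fn(residual).sum() / n_reg
    dpred[mask] = grad_fn(residual) / n_reg
    return float(loss), dpred


def detection_loss(cls_loss: float, reg_loss: float,
                   params: LossParams) -> float:
    """Total multi-task loss: L_cls/N_cls + lam * L_reg/N_reg.

    The terms are expected already normalized by their own counts (as
    produced by :func:`classification_loss` and :func:`regression_loss`);
    this merely applies the task-balance weight.
    """
    return float(cls_loss) + params.lam * float(reg_loss)


# --------------------------------------------------------------------------
# box-delta encoding (Faster R-CNN parameterization over x, y, w, h)
# --------------------------------------------------------------------------

def encode_box_deltas(anchors: np.ndarray, gt: np.ndarray) -> np.ndarray:
    """(dx, dy, dw, dh) taking each anchor onto its ground-truth box.

    dx = (gx - ax) / aw, dy = (gy - ay) / ah, dw = ln(gw / aw),
    dh = ln(gh / ah), with (ax, ay, aw, ah) the anchor centre and size.
    """
    anchors = np.asarray(anchors, dtype=float).reshape(-1, 4)
    gt = np.asarray(gt, dtype=float).reshape(-1, 4)
    aw = anchors[:, 2] - anchors[:, 0]
    ah = anchors[:, 3] - anchors[:, 1]
    if np.any(aw <= 0) or np.any(ah <= 0):
        raise ValueError("degenerate anchor (non-positive width/height)")
    ax = anchors[:, 0] + 0.5 * aw
    ay = anchors[:, 1] + 0.5 * ah
    gw = gt[:, 2] - gt[:, 0]
    gh = gt[:, 3] - gt[:, 1]
    gx = gt[:, 0] + 0.5 * gw
    gy = gt[:, 1] + 0.5 * gh
    return np.stack([(gx - ax) / aw, (gy - ay) / ah,
                     np.log(gw / aw), np.log(gh / ah)], axis=1)


def decode_box_deltas(anchors: np.ndarray, deltas: np.ndarray) -> np.ndarray:
    """Inverse of :func:`encode_box_deltas`."""
    anchors = np.asarray(anchors, dtype=float).reshape(-1, 4)
    deltas = np.asarray(deltas, dtype=float).reshape(-1, 4)
    aw = anchors[:, 2] - anchors[:, 0]
    ah = anchors[:, 3] - anchors[:, 1]
    ax = anchors[:, 0] + 0.5 * aw
    ay = anchors[:, 1] + 0.5 * ah
    # clamp dw/dh so exp cannot overflow on untrained predictions
    dw = np.clip(deltas[:, 2], -20.0, 20.0)
    dh = np.clip(deltas[:, 3], -20.0, 20.0)
    cx = ax + deltas[:, 0] * aw
    cy = ay + deltas[:, 1] * ah
    w = aw * np.exp(dw)
    h = ah * np.exp(dh)
    return np.stack([cx - 0.5 * w, cy - 0.5 * h,
                     cx + 0.5 * w, cy + 0.5 * h], axis=1)
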