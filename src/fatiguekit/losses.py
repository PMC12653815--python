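"""Bounding-box regression measures and the attention kernel-size rule.

Standalone detection-side math: IoU, the CIoU loss (overlap +
centre-distance + aspect-ratio penalties), the EIoU loss (which replaces
the aspect-ratio coupling with direct width and height regression), and
the channel-count -> odd-kernel-size mapping used by mixed local channel
attention.  Boxes are centre/width/height in any consistent length unit;
the math is coordinate-free.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple

__all__ = [
    "BoundingBox", "LossBreakdown",
    "iou", "ciou_loss", "eiou_loss", "mlca_kernel_size",
]


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box as centre (bx, by) with width and height > 0."""

    bx: float
    by: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if not (self.w > 0 and self.h > 0):
            raise ValueError(f"box sides must be positive, got w={self.w}, h={self.h}")
        if not all(math.isfinite(v) for v in (self.bx, self.by, self.w, self.h)):
            raise ValueError("box fields must be finite")

    @property
    def x1(self) -> float:
        return self.bx - self.w / 2

    @property
    def y1(self) -> float:
        return self.by - self.h / 2

    @property
    def x2(self) -> float:
        return self.bx + self.w / 2

    @property
    def y2(self) -> float:
        return self.by + self.h / 2

    @property
    def area(self) -> float:
        return self.w * self.h

    @classmethod
    def from_corners(cls, x1: float, y1: float, x2: float, y2: float
                     ) -> "BoundingBox":
        return cls((x1 + x2) / 2, (y1 + y2) / 2, x2 - x1, y2 - y1)

    def corners(self) -> Tuple[float, float, float, float]:
        return (self.x1, self.y1, self.x2, self.y2)


@dataclass(frozen=True)
class LossBreakdown:
    """EIoU loss terms: total = l_iou + l_dis + l_asp."""

    iou: float
    l_iou: float
    l_dis: float
    l_asp: float

    @property
    def total(self) -> float:
        return self.l_iou + self.l_dis + self.l_asp


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union, in [0, 1]; symmetric."""
    if (a.bx, a.by, a.w, a.h) == (b.bx, b.by, b.w, b.h):
        return 1.0      # exact, so the losses vanish iff boxes coincide
    iw = min(a.x2, b.x2) - max(a.x1, b.x1)
    ih = min(a.y2, b.y2) - max(a.y1, b.y1)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    # rounding can push inter/(union) one ulp past 1 for identical boxes
    return min(1.0, inter / (a.area + b.area - inter))


def _enclosing(a: BoundingBox, b: BoundingBox) -> Tuple[float, float]:
    wc = max(a.x2, b.x2) - min(a.x1, b.x1)
    hc = max(a.y2, b.y2) - min(a.y1, b.y1)
    return wc, hc


def ciou_loss(pred: BoundingBox, gt: BoundingBox) -> float:
    """CIoU loss: 1 - IoU + centre-distance and aspect-ratio penalties.

    ``1 - IoU + rho^2 / c^2 + alpha * v`` with rho the centre distance,
    c the enclosing-box diagonal, ``v = (4/pi^2)(atan(wg/hg) - atan(w/h))^2``
    and ``alpha = v / ((1 - IoU) + v)`` (zero when both vanish).
    """
    i = iou(pred, gt)
    wc, hc = _enclosing(pred, gt)
    rho2 = (pred.bx - gt.bx) ** 2 + (pred.by - gt.by) ** 2
    c2 = wc * wc + hc * hc
    v = (4.0 / math.pi**2) * (math.atan(gt.w / gt.h) - math.atan(pred.w / pred.h)) ** 2
    denom = (1.0 - i) + v
    alpha = v / denom if denom > 0 else 0.0
    return (1.0 - i) + rho2 / c2 + alpha * v


def eiou_loss(pred: BoundingBox, gt: BoundingBox) -> LossBreakdown:
    """EIoU loss with its three-term breakdown.

    ``1 - IoU`` plus the centre-distance penalty over the enclosing
    diagonal squared, plus direct width and height penalties over the
    enclosing width / height squared.
    """
    i = iou(pred, gt)
    wc, hc = _enclosing(pred, gt)
    rho2 = (pred.bx - gt.bx) ** 2 + (pred.by - gt.by) ** 2
    l_dis = rho2 / (wc * wc + hc * hc)
    l_asp = (pred.w - gt.w) ** 2 / (wc * wc) + (pred.h - gt.h) ** 2 / (hc * hc)
    return LossBreakdown(iou=i, l_iou=1.0 - i, l_dis=l_dis, l_asp=l_asp)


def mlca_kernel_size(channels: int, gamma: float = 2.0, b: float = 2.0) -> int:
    """Map a channel count to an odd 1-D attention kernel size.

    ``k = |log2(C)/gamma + b/gamma|_odd`` — the nearest odd integer to
    the bracketed value; an exact tie (the value landing on an even
    integer) rounds up to the larger odd neighbour.
    """
    if channels < 1:
        raise ValueError(f"channel count must be >= 1, got {channels}")
    t = abs(math.log2(channels) / gamma + b / gamma)
    lower = max(1, 2 * math.floor((t - 1) / 2) + 1)   # largest odd <= t (min 1)
    upper = lower + 2
    if t - lower < upper - t:
        return lower
    return upper
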