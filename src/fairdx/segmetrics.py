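"""Segmentation and annotation agreement metrics.

Pixel coordinates are 0-based; a box with corner (x0, y0) and size (w, h)
covers the half-open region [x0, x0+w) x [y0, y0+h), so its area is
exactly w*h.  Dice, IoU and Cohen's kappa operate on binary masks of equal
shape.  The precision/recall- and mAP-derived quantities are labelled
proxies: they are reported separately and never substituted for geometric
IoU.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AgreementResult",
    "BBox",
    "bbox_iou",
    "cohens_kappa",
    "iou_avg",
    "iou_from_pr",
    "mask_dice",
    "mask_iou",
    "read_bboxes_csv",
    "read_mask_png",
    "write_metrics_csv",
]


@dataclass(frozen=True)
class BBox:
    """Axis-aligned pixel bounding box, half-open extents."""

    x0: int
    y0: int
    w: int
    h: int

    def __post_init__(self) -> None:
        if self.w < 1 or self.h < 1:
            raise ValueError(f"box must have w, h >= 1, got ({self.w}, {self.h})")

    @property
    def area(self) -> int:
        return self.w * self.h


def bbox_iou(a: BBox, b: BBox) -> float:
    """Intersection over union of two pixel boxes; 0 when disjoint."""
    ix = max(0, min(a.x0 + a.w, b.x0 + b.w) - max(a.x0, b.x0))
    iy = max(0, min(a.y0 + a.h, b.y0 + b.h) - max(a.y0, b.y0))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union


def _as_binary_pair(pred, gt) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(pred)
    g = np.asarray(gt)
    if p.shape != g.shape:
        raise ValueError(f"mask shapes differ: {p.shape} vs {g.shape}")
    if p.size == 0:
        raise ValueError("masks are empty arrays")
    for name, m in (("pred", p), ("gt", g)):
        if not np.all(np.isin(m, [0, 1])):
            raise ValueError(f"{name} mask must be binary 0/1")
    return p.astype(bool), g.astype(bool)


def mask_dice(pred, gt) -> float:
    """Dice coefficient 2|A&B| / (|A| + |B|) of two binary masks."""
    p, g = _as_binary_pair(pred, gt)
    total = int(p.sum()) + int(g.sum())
    if total == 0:
        raise ValueError("both masks empty: Dice undefined")
    return 2.0 * int((p & g).sum()) / total


def mask_iou(pred, gt) -> float:
    """Jaccard index |A&B| / |A|B| of two binary masks."""
    p, g = _as_binary_pair(pred, gt)
    union = int((p | g).sum())
    if union == 0:
        raise ValueError("both masks empty: IoU undefined")
    return int((p & g).sum()) / union


@dataclass(frozen=True)
class AgreementResult:
    """Observed/expected agreement and the chance-corrected kappa."""

    po: float
    pe: float
    kappa: float


def cohens_kappa(a, b) -> AgreementResult:
    """Cohen's kappa between two binary annotations.

    po is the fraction of agreeing pixels; pe the agreement expected from
    the two marginal label distributions; kappa = (po - pe) / (1 - pe).
    When both masks are constant and identical (pe = 1, po = 1) kappa is
    defined as 1.
    """
    p, g = _as_binary_pair(a, b)
    n = p.size
    po = float((p == g).sum()) / n
    pa1, pb1 = float(p.sum()) / n, float(g.sum()) / n
    pe = pa1 * pb1 + (1.0 - pa1) * (1.0 - pb1)
    if pe == 1.0:
        kappa = 1.0  # both constant; po < 1 impossible for binary masks
    else:
        kappa = (po - pe) / (1.0 - pe)
    return AgreementResult(po=po, pe=pe, kappa=kappa)


def iou_from_pr(precision: float, recall: float) -> float:
    """Precision/recall proxy (precision + recall) / 2 — not geometric IoU."""
    for name, v in (("precision", precision), ("recall", recall)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0,1], got {v}")
    return (precision + recall) / 2.0


def iou_avg(map50: float, map50_95: float) -> float:
    """mAP proxy (mAP50 + mAP50_95) / 2 — not geometric IoU."""
    for name, v in (("map50", map50), ("map50_95", map50_95)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0,1], got {v}")
    return (map50 + map50_95) / 2.0


# --------------------------------------------------------------------------
# IO

def read_mask_png(path, threshold: int = 128) -> np.ndarray:
    """Read a grayscale PNG as a binary mask (foreground >= threshold)."""
    from PIL import Image

    arr = np.asarray(Image.open(path).convert("L"))
    return (arr >= threshold).astype(np.uint8)


def read_bboxes_csv(path) -> list[tuple[str, BBox]]:
    """Read (name, BBox) pairs from an annotation CSV.

    Expects columns label, x0, y0, w, h, name, img_shape_x, img_shape_y.
    """
    df = pd.read_csv(path)
    required = {"label", "x0", "y0", "w", "h", "name"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation CSV missing columns: {sorted(missing)}")
    return [
        (str(row["name"]), BBox(int(row["x0"]), int(row["y0"]), int(row["w"]), int(row["h"])))
        for row in df.to_dict("records")
    ]


def write_metrics_csv(rows: Sequence[dict], path) -> None:
    """Write per-image metric rows (name, dice, iou, kappa) as CSV."""
    pd.DataFrame(list(rows), columns=["name", "dice", "iou", "kappa"]).to_csv(
        path, index=False
    )
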