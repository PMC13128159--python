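"""Training losses: CIoU box regression and the composite detection loss.

The box term is complete-IoU: ``1 - IoU + rho^2/c^2 + alpha*v`` where ``rho``
is the center distance, ``c`` the enclosing-box diagonal, ``v`` the
aspect-ratio penalty ``(4/pi^2) (atan(w_g/h_g) - atan(w/h))^2`` and
``alpha = v / (1 - IoU + v)``.  The composite loss is the host family's
weighted sum of binary cross-entropy classification, CIoU box regression and
distribution-focal regression over assigned anchors.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np

from .nn import Tensor, cat

DEFAULT_LOSS_WEIGHTS = dict(box=7.5, cls=0.5, dfl=1.5)


# ---------------------------------------------------------------------------
# CIoU
# ---------------------------------------------------------------------------

def ciou_loss(box_pred: Sequence[float], box_gt: Sequence[float]) -> float:
    """Complete-IoU loss between two xyxy boxes (scalar, >= 0)."""
    x1, y1, x2, y2 = map(float, box_pred)
    g1, h1, g2, h2 = map(float, box_gt)
    w, h = x2 - x1, y2 - y1
    wg, hg = g2 - g1, h2 - h1
    if w <= 0 or h <= 0 or wg <= 0 or hg <= 0:
        raise ValueError("degenerate (non-positive area) box")
    iw = max(0.0, min(x2, g2) - max(x1, g1))
    ih = max(0.0, min(y2, h2) - max(y1, h1))
    inter = iw * ih
    union = w * h + wg * hg - inter
    iou = inter / union
    cx, cy = (x1 + x2) / 2, (y1 + y2) / 2
    gx, gy = (g1 + g2) / 2, (h1 + h2) / 2
    rho2 = (cx - gx) ** 2 + (cy - gy) ** 2
    ex1, ey1 = min(x1, g1), min(y1, h1)
    ex2, ey2 = max(x2, g2), max(y2, h2)
    c2 = (ex2 - ex1) ** 2 + (ey2 - ey1) ** 2
    v = (4 / math.pi ** 2) * (math.atan(wg / hg) - math.atan(w / h)) ** 2
    alpha = 0.0 if v == 0 else v / (1 - iou + v)
    return 1 - iou + rho2 / c2 + alpha * v


def ciou_loss_tensor(pred: Tensor, gt: np.ndarray, eps: float = 1e-7) -> Tensor:
    """Vectorized differentiable CIoU: pred (N,4) tensor, gt (N,4) array."""
    gt = np.asarray(gt, dtype=np.float32)
    px1, py1, px2, py2 = (pred[:, i] for i in range(4))
    gx1, gy1, gx2, gy2 = (Tensor(gt[:, i]) for i in range(4))
    pw = (px2 - px1); ph = (py2 - py1)
    gw = (gx2 - gx1); gh = (gy2 - gy1)
    iw = _minimum(px2, gx2) - _maximum(px1, gx1)
    ih = _minimum(py2, gy2) - _maximum(py1, gy1)
    iw = iw.relu(); ih = ih.relu()
    inter = iw * ih
    union = pw * ph + gw * gh - inter + eps
    iou = inter / union
    rho2 = ((px1 + px2 - gx1 - gx2) ** 2 + (py1 + py2 - gy1 - gy2) ** 2) * 0.25
    cw = _maximum(px2, gx2) - _minimum(px1, gx1)
    chh = _maximum(py2, gy2) - _minimum(py1, gy1)
    c2 = cw * cw + chh * chh + eps
    v = ((gw / (gh + eps)).arctan() - (pw / (ph + eps)).arctan())
    v = v * v * (4 / math.pi ** 2)
    alpha = Tensor(v.data / (1 - iou.data + v.data + eps))  # treated as constant
    return 1 - iou + rho2 / c2 + alpha * v


def _maximum(a: Tensor, b: Tensor) -> Tensor:
    return (a - b).relu() + b


def _minimum(a: Tensor, b: Tensor) -> Tensor:
    return a - (a - b).relu()


# ---------------------------------------------------------------------------
# BCE with logits
# ---------------------------------------------------------------------------

def bce_with_logits(x: Tensor, target: np.ndarray) -> Tensor:
    """Numerically stable element-wise binary cross-entropy on logits."""
    t = Tensor(np.asarray(target, dtype=np.float32))
    ax = x.relu() + (-x).relu()
    return x.relu() - x * t + ((-ax).exp() + 1.0).log()


# ---------------------------------------------------------------------------
# Target assignment (center-prior) and composite loss
# ---------------------------------------------------------------------------

def anchor_points(sizes: Sequence[tuple[int, int]],
                  strides: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    """Cell-center coordinates and per-anchor stride, concatenated over scales."""
    pts, sts = [], []
    for (h, w), s in zip(sizes, strides):
        gy, gx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        pts.append(np.stack([(gx.reshape(-1) + 0.5) * s,
                             (gy.reshape(-1) + 0.5) * s], axis=1))
        sts.append(np.full(h * w, s, dtype=np.float32))
    return np.concatenate(pts).astype(np.float32), np.concatenate(sts)


def assign_targets(gt_boxes: np.ndarray, pts: np.ndarray, strides: np.ndarray,
                   topk: int = 9) -> np.ndarray:
    """Greedy center-prior assignment.

    For each ground-truth box, anchors whose point lies inside the box are
    candidates; the ``topk`` closest to the box center are positives.  An
    anchor claimed by several boxes goes to the one with the nearest center.
    Returns an int array (A,) with the GT index per anchor or -1.
    """
    a = len(pts)
    assign = np.full(a, -1, dtype=np.int64)
    best_d = np.full(a, np.inf, dtype=np.float32)
    for gi, (x1, y1, x2, y2) in enumerate(gt_boxes):
        inside = ((pts[:, 0] > x1) & (pts[:, 0] < x2)
                  & (pts[:, 1] > y1) & (pts[:, 1] < y2))
        idx = np.flatnonzero(inside)
        if idx.size == 0:
            idx = np.array([np.argmin(
                (pts[:, 0] - (x1 + x2) / 2) ** 2 + (pts[:, 1] - (y1 + y2) / 2) ** 2)])
        cx, cy = (x1 + x2) / 2, (y1 + y2) / 2
        d = (pts[idx, 0] - cx) ** 2 + (pts[idx, 1] - cy) ** 2
        order = np.argsort(d, kind="stable")[:topk]
        for o in order:
            ai = idx[o]
            if d[o] < best_d[ai]:
                best_d[ai] = d[o]
                assign[ai] = gi
    return assign


def composite_detection_loss(raw_preds: list[Tensor],
                             targets: list[np.ndarray],
                             nc: int, reg_max: int,
                             strides: Sequence[int] = (8, 16, 32),
                             weights: Optional[dict] = None):
    """Weighted cls + CIoU + DFL loss for one batch.

    ``raw_preds``: per-scale maps (N, 4*reg_max+nc, H, W).
    ``targets``: per image an (M, 5) array of (class, x1, y1, x2, y2) in
    network input pixels.
    Returns (total loss tensor, dict of detached per-term values).
    """
    w = dict(DEFAULT_LOSS_WEIGHTS)
    if weights:
        w.update(weights)
    n = raw_preds[0].data.shape[0]
    sizes = [(p.data.shape[2], p.data.shape[3]) for p in raw_preds]
    pts, sts = anchor_points(sizes, strides)
    # flatten to (N, C, A)
    flat = cat([p.reshape(p.data.shape[0], p.data.shape[1],
                          p.data.shape[2] * p.data.shape[3])
                for p in raw_preds], axis=2)
    a = flat.data.shape[2]
    box_logits = flat[:, : 4 * reg_max]
    cls_logits = flat[:, 4 * reg_max:]

    cls_target = np.zeros((n, nc, a), dtype=np.float32)
    pos: list[tuple[int, np.ndarray, np.ndarray]] = []
    n_pos = 0
    for bi in range(n):
        t = np.asarray(targets[bi], dtype=np.float32).reshape(-1, 5)
        if len(t) == 0:
            continue
        assign = assign_targets(t[:, 1:], pts, sts)
        mask = assign >= 0
        ai = np.flatnonzero(mask)
        if ai.size == 0:
            continue
        gi = assign[ai]
        cls_target[bi, t[gi, 0].astype(int), ai] = 1.0
        pos.append((bi, ai, gi))
        n_pos += ai.size

    cls_loss = bce_with_logits(cls_logits, cls_target).sum() / max(n_pos, 1)

    if n_pos == 0:
        zero = Tensor(np.zeros(()))
        total = cls_loss * w["cls"]
        return total, {"cls": float(cls_loss.data), "box": 0.0, "dfl": 0.0,
                       "total": float(total.data), "n_pos": 0}

    box_terms, dfl_terms = [], []
    proj = Tensor(np.arange(reg_max, dtype=np.float32).reshape(1, 1, reg_max))
    for bi, ai, gi in pos:
        t = np.asarray(targets[bi], dtype=np.float32).reshape(-1, 5)
        gt = t[gi, 1:]                              # (P,4) xyxy pixels
        p_pts, p_sts = pts[ai], sts[ai]
        logits = box_logits[bi][:, ai]              # (4*reg_max, P)
        dist = logits.reshape(4, reg_max, len(ai)).transpose(0, 2, 1)  # (4,P,reg)
        prob = dist.softmax(axis=2)
        d = (prob * proj).sum(axis=2)               # (4, P) in stride units
        px1 = p_pts[:, 0] - d[0] * p_sts
        py1 = p_pts[:, 1] - d[1] * p_sts
        px2 = p_pts[:, 0] + d[2] * p_sts
        py2 = p_pts[:, 1] + d[3] * p_sts
        from .nn import stack as _stack
        pred_boxes = _stack([px1, py1, px2, py2], axis=1)
        box_terms.append(ciou_loss_tensor(pred_boxes, gt).sum())
        # DFL on target distances in stride units, clipped into the bin range
        tl = np.stack([(p_pts[:, 0] - gt[:, 0]) / p_sts,
                       (p_pts[:, 1] - gt[:, 1]) / p_sts,
                       (gt[:, 2] - p_pts[:, 0]) / p_sts,
                       (gt[:, 3] - p_pts[:, 1]) / p_sts], axis=0)
        tl = np.clip(tl, 0, reg_max - 1 - 1e-3)
        lo = np.floor(tl).astype(int)
        hi = lo + 1
        w_hi = tl - lo
        w_lo = 1.0 - w_hi
        logp = (prob + 1e-9).log()                  # (4, P, reg)
        i0, i1 = np.indices(tl.shape)
        dfl = -(logp[i0, i1, lo] * w_lo + logp[i0, i1, hi] * w_hi)
        dfl_terms.append(dfl.sum())

    box_loss = _sum_tensors(box_terms) / n_pos
    dfl_loss = _sum_tensors(dfl_terms) / (4 * n_pos)
    total = cls_loss * w["cls"] + box_loss * w["box"] + dfl_loss * w["dfl"]
    for name, term in (("cls", cls_loss), ("box", box_loss), ("dfl", dfl_loss)):
        if not np.isfinite(term.data):
            raise FloatingPointError(f"non-finite {name} loss term")
    return total, {"cls": float(cls_loss.data), "box": float(box_loss.data),
                   "dfl": float(dfl_loss.data), "total": float(total.data),
                   "n_pos": n_pos}


def _sum_tensors(ts):
    out = ts[0]
    for t in ts[1:]:
        out = out + t
    return out
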