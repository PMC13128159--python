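"""Eigen-CAM saliency on the feature maps feeding the detection head.

The map for a feature tensor F (C x H x W) is built from the top eigenvector
u1 of the channel Gram matrix F'F'^T (F' the C x HW unfolding): the raw map
is the u1-weighted channel sum, its sign fixed so the spatial sum is
non-negative, then ReLU, min-max normalization and bilinear upsampling to
the input size.  Gradient-free and class-agnostic: it shows where the
learned features concentrate, which for a trained detector is the lesion
foreground.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np

from .nn import Tensor, no_grad
from .model import DetectionModel, letterbox_image, letterbox_params
from .phantom import Annotation

__all__ = ["Heatmap", "eigen_cam", "eigen_cam_for_image", "overlay_heatmap",
           "localization_score"]


@dataclasses.dataclass
class Heatmap:
    values: np.ndarray          # (H, W) in [0, 1]
    source: str = ""


def eigen_cam_raw(feature) -> np.ndarray:
    """Sign-fixed, rectified principal-component map, not yet normalized."""
    f = np.asarray(feature, dtype=np.float64)
    if isinstance(feature, Tensor):
        f = feature.data.astype(np.float64)
    if f.ndim == 4:
        if f.shape[0] != 1:
            raise ValueError("pass a single feature map, not a batch")
        f = f[0]
    if not np.isfinite(f).all():
        raise ValueError("non-finite feature map")
    c, h, w = f.shape
    if h * w < 2:
        raise ValueError("need at least 2 spatial positions")
    flat = f.reshape(c, h * w)
    if not flat.any():
        return np.zeros((h, w))
    gram = flat @ flat.T
    _, vecs = np.linalg.eigh(gram)
    u1 = vecs[:, -1]                           # eigenvector of largest eigenvalue
    m = (u1[:, None] * flat).sum(axis=0).reshape(h, w)
    if m.sum() < 0:
        m = -m
    return np.maximum(m, 0.0)


def _minmax(m: np.ndarray) -> np.ndarray:
    lo, hi = m.min(), m.max()
    return (m - lo) / (hi - lo) if hi > lo else np.zeros_like(m)


def eigen_cam(feature: np.ndarray, output_size: Optional[tuple[int, int]] = None,
              source: str = "") -> Heatmap:
    """Saliency map of one C x H x W activation tensor."""
    m = _minmax(eigen_cam_raw(feature))
    if output_size is not None and output_size != m.shape:
        m = _minmax(_bilinear_resize(m, output_size))
    return Heatmap(m.astype(np.float32), source)


def _bilinear_resize(a: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    h, w = a.shape
    oh, ow = size
    ys = (np.arange(oh) + 0.5) * h / oh - 0.5
    xs = (np.arange(ow) + 0.5) * w / ow - 0.5
    y0 = np.clip(np.floor(ys).astype(int), 0, h - 1)
    x0 = np.clip(np.floor(xs).astype(int), 0, w - 1)
    y1 = np.clip(y0 + 1, 0, h - 1)
    x1 = np.clip(x0 + 1, 0, w - 1)
    wy = np.clip(ys - y0, 0, 1)[:, None]
    wx = np.clip(xs - x0, 0, 1)[None, :]
    return (a[np.ix_(y0, x0)] * (1 - wy) * (1 - wx)
            + a[np.ix_(y1, x0)] * wy * (1 - wx)
            + a[np.ix_(y0, x1)] * (1 - wy) * wx
            + a[np.ix_(y1, x1)] * wy * wx)


def eigen_cam_for_image(model: DetectionModel, image: np.ndarray) -> Heatmap:
    """Combined saliency over the three head-input streams.

    The raw (rectified, sign-fixed, un-normalized) principal-component map
    of each stream is bilinearly upsampled to the input size and the three
    are summed before a single min-max normalization.  Summing raw maps
    preserves the relative activation energy of the streams; normalizing
    per stream first would let a weakly activated coarse stream contribute
    spurious hotspots.
    """
    img = np.asarray(image, dtype=np.float32)
    if img.ndim == 2:
        img = img[None]
    h, w = img.shape[1], img.shape[2]
    size = model.img_size
    x = letterbox_image(img, size)[None]
    keep = set(model.head_input_indices())
    model.eval()
    with no_grad():
        _, kept = model(Tensor(x), keep=keep)
    r, dx, dy = letterbox_params(h, w, size)
    combined = np.zeros((h, w), dtype=np.float64)
    for idx, feat in kept.items():
        raw = eigen_cam_raw(feat.data[0])
        up = _bilinear_resize(raw, (size, size))
        # crop letterbox padding back to the original frame
        y0, x0 = int(round(dy)), int(round(dx))
        nh, nw = round(h * r), round(w * r)
        combined += _bilinear_resize(up[y0:y0 + nh, x0:x0 + nw], (h, w))
    return Heatmap(_minmax(combined).astype(np.float32), "head_sum")


# blue -> red colormap anchors (cold to hot)
_CMAP = np.array([[0.0, 0.0, 0.55], [0.0, 0.45, 0.95], [0.0, 0.85, 0.65],
                  [0.75, 0.95, 0.15], [1.0, 0.55, 0.0], [0.85, 0.0, 0.0]])


def overlay_heatmap(image: np.ndarray, heatmap: Heatmap,
                    alpha: float = 0.5) -> np.ndarray:
    """Alpha-blend a blue-to-red rendering of the heatmap onto a gray image.

    Returns an (H, W, 3) float array in [0, 1].
    """
    img = np.asarray(image, dtype=np.float64)
    hm = heatmap.values if isinstance(heatmap, Heatmap) else np.asarray(heatmap)
    if img.shape != hm.shape:
        raise ValueError(f"size mismatch: image {img.shape} vs heatmap {hm.shape}")
    pos = np.clip(hm, 0, 1) * (len(_CMAP) - 1)
    lo = np.floor(pos).astype(int)
    hi = np.clip(lo + 1, 0, len(_CMAP) - 1)
    t = (pos - lo)[..., None]
    colored = _CMAP[lo] * (1 - t) + _CMAP[hi] * t
    gray = np.repeat(img[..., None], 3, axis=2)
    return ((1 - alpha) * gray + alpha * colored).astype(np.float32)


def localization_score(heatmap: Heatmap, boxes: Sequence[Annotation],
                       activation_quantile: float = 0.95) -> float:
    """Fraction of top-quantile heat pixels inside any ground-truth box."""
    if not boxes:
        raise ValueError("localization_score needs at least one box")
    hm = heatmap.values if isinstance(heatmap, Heatmap) else np.asarray(heatmap)
    h, w = hm.shape
    inside = np.zeros((h, w), dtype=bool)
    for b in boxes:
        x1, y1, x2, y2 = b.box
        inside[int(np.floor(y1)):int(np.ceil(y2)),
               int(np.floor(x1)):int(np.ceil(x2))] = True
    if hm.min() == hm.max():        # degenerate: flat map -> all pixels
        return float(inside.mean())
    thr = np.quantile(hm, activation_quantile)
    top = hm > thr
    if not top.any():               # plateau at the maximum value
        top = hm >= thr
    return float(inside[top].sum() / top.sum())
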