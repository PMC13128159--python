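"""Synthetic MRI-like phantom generator and YOLO-format label I/O.

Each phantom is a single-channel slice: a textured bright ellipse (the
"head") on a dark background, zero to a few blurred, anisotropic Gaussian
"tumor" blobs brighter than their surroundings, and additive Gaussian noise.
The construction mirrors the failure modes the detector targets — blurred
lesion boundaries and modest lesion/background contrast — while keeping
exact ground truth: every blob's bounding box is derived analytically from
the half-contrast level set of its (blurred) Gaussian profile.

Boxes are 0-based half-open pixel rectangles internally; the normalized
YOLO center format appears only at file boundaries.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

__all__ = [
    "PhantomSpec", "Annotation", "generate_phantom", "write_yolo_labels",
    "read_yolo_labels", "save_yolo_labels", "load_yolo_labels",
    "build_dataset", "load_image", "save_image", "per_image_seed",
]

_HALF_LEVEL = 2.0 * np.log(2.0)      # q with exp(-q/2) = 1/2


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Study conditions for one phantom image family."""

    image_size: int = 128
    tumor_count_range: tuple[int, int] = (0, 3)
    tumor_radius_range: tuple[float, float] = (6.0, 14.0)
    tumor_contrast_range: tuple[float, float] = (0.25, 0.6)
    edge_blur_sigma: float = 2.0
    background_texture_scale: float = 12.0
    noise_sigma: float = 0.03

    def __post_init__(self):
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        lo, hi = self.tumor_count_range
        if not (0 <= lo <= hi):
            raise ValueError("invalid tumor_count_range")
        rlo, rhi = self.tumor_radius_range
        if not (0 < rlo <= rhi):
            raise ValueError("tumor radius interval must be positive")
        clo, chi = self.tumor_contrast_range
        if not (0 < clo <= chi <= 1):
            raise ValueError("contrast interval must lie in (0, 1]")
        if self.noise_sigma < 0 or self.edge_blur_sigma < 0:
            raise ValueError("sigmas must be non-negative")


@dataclasses.dataclass(frozen=True)
class Annotation:
    """One object: class id and half-open pixel box (x right, y down)."""

    class_id: int
    box: tuple[float, float, float, float]    # x1, y1, x2, y2

    def validate(self, width: int, height: int) -> "Annotation":
        x1, y1, x2, y2 = self.box
        if not (0 <= x1 < x2 <= width and 0 <= y1 < y2 <= height):
            raise ValueError(f"invalid box {self.box} for {width}x{height}")
        return self


class PlacementError(RuntimeError):
    """A blob could not be placed inside the head ellipse."""


def _blob_field(size: int, cx: float, cy: float, cov: np.ndarray,
                amplitude: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    d = np.stack([xx - cx, yy - cy], axis=-1)
    icov = np.linalg.inv(cov)
    q = (d @ icov * d).sum(axis=-1)
    return (amplitude * np.exp(-0.5 * q)).astype(np.float64)


def _blob_geometry(rx: float, ry: float, angle: float, blur: float):
    """Effective covariance and amplitude attenuation after Gaussian blur."""
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    cov = rot @ np.diag([rx ** 2, ry ** 2]) @ rot.T
    cov_eff = cov + (blur ** 2) * np.eye(2)
    atten = np.sqrt(np.linalg.det(cov) / np.linalg.det(cov_eff))
    return cov_eff, atten


def _head_mask_and_texture(spec: PhantomSpec, rng: np.random.Generator):
    size = spec.image_size
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    cx = cy = (size - 1) / 2.0
    ax, ay = 0.46 * size, 0.40 * size
    r2 = ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2
    mask = r2 <= 1.0
    tex = rng.normal(size=(size, size))
    tex = gaussian_filter(tex, spec.background_texture_scale, mode="reflect")
    std = tex.std()
    if std > 0:
        tex = tex / std
    base = 0.35 + 0.06 * tex
    img = np.where(mask, base, 0.02)
    # soften the skull edge a little so it is not a step
    img = gaussian_filter(img, 1.0, mode="reflect")
    return img, (cx, cy, ax, ay)


def _fits_head(box, head) -> bool:
    cx, cy, ax, ay = head
    x1, y1, x2, y2 = box
    for px, py in ((x1, y1), (x1, y2), (x2, y1), (x2, y2)):
        if ((px - cx) / ax) ** 2 + ((py - cy) / ay) ** 2 > 0.92:
            return False
    return True


def generate_phantom(spec: PhantomSpec, seed: int, *, return_fields: bool = False):
    """Render one phantom; deterministic for a fixed (spec, seed).

    Returns ``(image, annotations)`` with the image in [0, 1]; with
    ``return_fields=True`` also the list of per-blob noiseless fields used
    by oracle tests.
    """
    if seed < 0:
        raise ValueError("seed must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence([17, int(seed)]))
    img, head = _head_mask_and_texture(spec, rng)
    n = int(rng.integers(spec.tumor_count_range[0], spec.tumor_count_range[1] + 1))
    size = spec.image_size
    annotations: list[Annotation] = []
    fields: list[np.ndarray] = []
    boxes: list[tuple] = []
    for _ in range(n):
        placed = False
        for _attempt in range(60):
            rx = rng.uniform(*spec.tumor_radius_range)
            ry = rng.uniform(*spec.tumor_radius_range)
            angle = rng.uniform(0, np.pi)
            contrast = rng.uniform(*spec.tumor_contrast_range)
            cov, atten = _blob_geometry(rx, ry, angle, spec.edge_blur_sigma)
            hw = np.sqrt(_HALF_LEVEL * cov[0, 0])
            hh = np.sqrt(_HALF_LEVEL * cov[1, 1])
            if 2 * hw >= size or 2 * hh >= size:
                continue          # blob larger than the frame: retry
            cx = rng.uniform(hw, size - hw)
            cy = rng.uniform(hh, size - hh)
            box = (cx - hw, cy - hh, cx + hw, cy + hh)
            if not _fits_head(box, head):
                continue
            if boxes and _max_iou(box, boxes) > 0.2:
                continue
            field = _blob_field(size, cx, cy, cov, contrast * atten)
            img = img + field
            annotations.append(Annotation(0, box).validate(size, size))
            boxes.append(box)
            fields.append(field)
            placed = True
            break
        if not placed:
            raise PlacementError("could not place blob inside head ellipse")
    if spec.noise_sigma > 0:
        img = img + rng.normal(0, spec.noise_sigma, img.shape)
    img = np.clip(img, 0.0, 1.0).astype(np.float32)
    if return_fields:
        return img, annotations, fields
    return img, annotations


def _max_iou(box, others) -> float:
    x1, y1, x2, y2 = box
    best = 0.0
    for ox1, oy1, ox2, oy2 in others:
        iw = max(0.0, min(x2, ox2) - max(x1, ox1))
        ih = max(0.0, min(y2, oy2) - max(y1, oy1))
        inter = iw * ih
        union = (x2 - x1) * (y2 - y1) + (ox2 - ox1) * (oy2 - oy1) - inter
        if union > 0:
            best = max(best, inter / union)
    return best


# ---------------------------------------------------------------------------
# YOLO label dialect
# ---------------------------------------------------------------------------

def write_yolo_labels(annotations: Sequence[Annotation], image_width: int,
                      image_height: int) -> str:
    """Serialize to ``class cx cy w h`` lines, normalized, 6 decimals."""
    lines = []
    for a in annotations:
        a.validate(image_width, image_height)
        x1, y1, x2, y2 = a.box
        cx = (x1 + x2) / 2.0 / image_width
        cy = (y1 + y2) / 2.0 / image_height
        w = (x2 - x1) / image_width
        h = (y2 - y1) / image_height
        lines.append(f"{a.class_id} {cx:.6f} {cy:.6f} {w:.6f} {h:.6f}")
    return "\n".join(lines) + ("\n" if lines else "")


def read_yolo_labels(records: str, image_width: int,
                     image_height: int) -> list[Annotation]:
    """Parse YOLO label text; raises ValueError naming the offending line."""
    out: list[Annotation] = []
    for ln, line in enumerate(records.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 5:
            raise ValueError(f"line {ln}: expected 5 fields, got {len(parts)}")
        try:
            cls = int(parts[0])
            cx, cy, w, h = (float(p) for p in parts[1:])
        except ValueError as e:
            raise ValueError(f"line {ln}: {e}") from None
        for name, v in (("cx", cx), ("cy", cy), ("w", w), ("h", h)):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"line {ln}: {name}={v} outside [0, 1]")
        x1 = (cx - w / 2) * image_width
        x2 = (cx + w / 2) * image_width
        y1 = (cy - h / 2) * image_height
        y2 = (cy + h / 2) * image_height
        x1, x2 = max(0.0, x1), min(float(image_width), x2)
        y1, y2 = max(0.0, y1), min(float(image_height), y2)
        out.append(Annotation(cls, (x1, y1, x2, y2)).validate(image_width, image_height))
    return out


def save_yolo_labels(path, annotations, image_width, image_height) -> None:
    Path(path).write_text(write_yolo_labels(annotations, image_width, image_height))


def load_yolo_labels(path, image_width, image_height) -> list[Annotation]:
    return read_yolo_labels(Path(path).read_text(), image_width, image_height)


def save_image(path, image: np.ndarray) -> None:
    """8-bit grayscale PNG."""
    q = np.clip(np.round(image * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(q, mode="L").save(path, format="PNG")


def load_image(path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=np.float32) / 255.0


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

def per_image_seed(master_seed: int, index: int) -> int:
    """Fixed hashing of (master seed, image index) -> per-image seed."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(int(index),))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def build_dataset(n_images: int, spec: PhantomSpec, seed: int, out_dir,
                  split: tuple[float, float, float] = (0.6, 0.2, 0.2)) -> dict:
    """Generate a train/val/test phantom dataset on disk; returns manifest."""
    if n_images < 3:
        raise ValueError("need at least 3 images for a 3-way split")
    if abs(sum(split) - 1.0) > 1e-6:
        raise ValueError("split fractions must sum to 1")
    out_dir = Path(out_dir)
    n_train = max(1, int(round(n_images * split[0])))
    n_val = max(1, int(round(n_images * split[1])))
    n_test = max(1, n_images - n_train - n_val)
    while n_train + n_val + n_test > n_images:
        n_train -= 1
    counts = {"train": n_train, "val": n_val, "test": n_test}
    manifest = {"n_images": n_images, "seed": int(seed),
                "spec": dataclasses.asdict(spec), "splits": {}}
    idx = 0
    for part, count in counts.items():
        img_dir = out_dir / part / "images"
        lbl_dir = out_dir / part / "labels"
        img_dir.mkdir(parents=True, exist_ok=True)
        lbl_dir.mkdir(parents=True, exist_ok=True)
        entries = []
        for _ in range(count):
            s = per_image_seed(seed, idx)
            image, anns = generate_phantom(spec, s)
            stem = f"phantom_{idx:05d}"
            save_image(img_dir / f"{stem}.png", image)
            save_yolo_labels(lbl_dir / f"{stem}.txt", anns,
                             spec.image_size, spec.image_size)
            digest = hashlib.sha256((img_dir / f"{stem}.png").read_bytes()).hexdigest()
            entries.append({"image": f"{part}/images/{stem}.png",
                            "label": f"{part}/labels/{stem}.txt",
                            "seed": s, "n_boxes": len(anns), "sha256": digest})
            idx += 1
        manifest["splits"][part] = entries
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def load_manifest(dataset_dir) -> dict:
    return json.loads((Path(dataset_dir) / "manifest.json").read_text())
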