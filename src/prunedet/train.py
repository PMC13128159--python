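"""Two-stage training protocol: initial training and the single post-prune
fine-tune.

The optimizer is SGD with momentum 0.937 and weight decay 5e-4 (host-family
defaults), learning rate 0.01, cosine-annealed by default.  Augmentation
follows the standard YOLO recipe — mosaic composition, random rotation and
scaling, horizontal flip and brightness (value-channel) jitter, generated
on the fly every epoch.  Validation runs after each epoch; early stopping
keeps the best checkpoint by validation mAP_0.5.

Two profiles ship: the paper-scale profile (640 px, 300 epochs, batch 16)
and a desk profile (128 px, width 0.125) sized for single-CPU runs; tests
and the synthetic pipeline exercise the desk profile only.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np

from .nn import Tensor
from .model import DetectionModel, predict, save_checkpoint
from .blocks import DynamicConv2d
from .losses import composite_detection_loss
from .metrics import mean_average_precision, dataset_recall
from .phantom import Annotation, load_image, load_yolo_labels, load_manifest


@dataclasses.dataclass
class AugmentConfig:
    mosaic: float = 1.0
    degrees: float = 10.0
    scale: float = 0.5
    fliplr: float = 0.5
    hsv_h: float = 0.015    # ignored for single-channel inputs
    hsv_s: float = 0.7      # ignored for single-channel inputs
    hsv_v: float = 0.4


@dataclasses.dataclass
class TrainConfig:
    epochs: int = 30
    batch_size: int = 8
    learning_rate: float = 0.01
    momentum: float = 0.937
    weight_decay: float = 5e-4
    lr_schedule: str = "cosine"           # step | cosine | cosine_restarts
    patience: int = 50
    input_size: int = 128
    seed: int = 0
    augment: AugmentConfig = dataclasses.field(default_factory=AugmentConfig)
    conf_threshold: float = 0.25
    warmup_epochs: int = 2
    tau_start: float = 30.0               # dynamic-conv softmax temperature

    def __post_init__(self):
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("invalid epochs/batch size")
        for p in (self.augment.mosaic, self.augment.fliplr):
            if not 0 <= p <= 1:
                raise ValueError("augmentation probabilities must be in [0,1]")


PAPER_SCALE = TrainConfig(epochs=300, batch_size=16, input_size=640, patience=50)
FINETUNE_DESK = TrainConfig(epochs=10, batch_size=8, input_size=128, patience=50)


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

def _affine_sample(img: np.ndarray, mat: np.ndarray) -> np.ndarray:
    """Inverse-mapped nearest-neighbour affine warp of a 2-D image."""
    h, w = img.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    inv = np.linalg.inv(mat)
    sx = inv[0, 0] * xx + inv[0, 1] * yy + inv[0, 2]
    sy = inv[1, 0] * xx + inv[1, 1] * yy + inv[1, 2]
    xi = np.round(sx).astype(int)
    yi = np.round(sy).astype(int)
    valid = (xi >= 0) & (xi < w) & (yi >= 0) & (yi < h)
    out = np.zeros_like(img)
    out[valid] = img[yi[valid], xi[valid]]
    return out


def _transform_boxes(anns: Sequence[Annotation], mat: np.ndarray,
                     w: int, h: int) -> list[Annotation]:
    out = []
    for a in anns:
        x1, y1, x2, y2 = a.box
        pts = np.array([[x1, y1, 1], [x2, y1, 1], [x1, y2, 1], [x2, y2, 1]]).T
        q = mat @ pts
        nx1, ny1 = q[0].min(), q[1].min()
        nx2, ny2 = q[0].max(), q[1].max()
        nx1, ny1 = max(0.0, nx1), max(0.0, ny1)
        nx2, ny2 = min(float(w), nx2), min(float(h), ny2)
        if nx2 - nx1 >= 2.0 and ny2 - ny1 >= 2.0:
            out.append(Annotation(a.class_id, (nx1, ny1, nx2, ny2)))
    return out


def augment(image: np.ndarray, annotations: Sequence[Annotation],
            config: AugmentConfig, rng: np.random.Generator,
            sampler: Optional[Callable[[], tuple[np.ndarray, list[Annotation]]]] = None
            ) -> tuple[np.ndarray, list[Annotation]]:
    """One stochastic augmentation draw; deterministic given the rng state."""
    img = np.asarray(image, dtype=np.float32)
    anns = list(annotations)
    h, w = img.shape

    if sampler is not None and config.mosaic > 0 and rng.random() < config.mosaic:
        canvas = np.zeros_like(img)
        merged: list[Annotation] = []
        hh, hw = h // 2, w // 2
        tiles = [(0, 0), (0, hw), (hh, 0), (hh, hw)]
        sources = [(img, anns)] + [sampler() for _ in range(3)]
        for (oy, ox), (tile_img, tile_anns) in zip(tiles, sources):
            th, tw = (hh, hw)
            yi = (np.arange(th) * tile_img.shape[0] / th).astype(int)
            xi = (np.arange(tw) * tile_img.shape[1] / tw).astype(int)
            canvas[oy:oy + th, ox:ox + tw] = tile_img[yi][:, xi]
            sy = th / tile_img.shape[0]
            sx = tw / tile_img.shape[1]
            for a in tile_anns:
                x1, y1, x2, y2 = a.box
                b = (x1 * sx + ox, y1 * sy + oy, x2 * sx + ox, y2 * sy + oy)
                if b[2] - b[0] >= 2 and b[3] - b[1] >= 2:
                    merged.append(Annotation(a.class_id, b))
        img, anns = canvas, merged

    # affine: rotation + isotropic scale about the image center
    deg = rng.uniform(-config.degrees, config.degrees) if config.degrees > 0 else 0.0
    sc = rng.uniform(1 - config.scale, 1 + config.scale) if config.scale > 0 else 1.0
    if deg != 0.0 or sc != 1.0:
        th = math.radians(deg)
        c, s = math.cos(th) * sc, math.sin(th) * sc
        cx, cy = (w - 1) / 2, (h - 1) / 2
        mat = np.array([[c, -s, cx - c * cx + s * cy],
                        [s, c, cy - s * cx - c * cy],
                        [0, 0, 1.0]])
        img = _affine_sample(img, mat)
        anns = _transform_boxes(anns, mat, w, h)

    if config.fliplr > 0 and rng.random() < config.fliplr:
        img = img[:, ::-1].copy()
        anns = [Annotation(a.class_id,
                           (w - a.box[2], a.box[1], w - a.box[0], a.box[3]))
                for a in anns]

    if config.hsv_v > 0:
        gain = 1.0 + rng.uniform(-config.hsv_v, config.hsv_v)
        img = np.clip(img * gain, 0.0, 1.0)
    return img.astype(np.float32), anns


# ---------------------------------------------------------------------------
# Dataset access
# ---------------------------------------------------------------------------

def load_split(dataset_dir, part: str) -> list[tuple[np.ndarray, list[Annotation]]]:
    root = Path(dataset_dir)
    manifest = load_manifest(root)
    size = manifest["spec"]["image_size"]
    out = []
    for entry in manifest["splits"][part]:
        img = load_image(root / entry["image"])
        anns = load_yolo_labels(root / entry["label"], size, size)
        out.append((img, anns))
    return out


# ---------------------------------------------------------------------------
# Optimizer and schedule
# ---------------------------------------------------------------------------

class SGD:
    def __init__(self, params, lr, momentum=0.937, weight_decay=5e-4):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.buf = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, b in zip(self.params, self.buf):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            b *= self.momentum
            b += g
            p.data = p.data - self.lr * b

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def lr_factor(schedule: str, epoch: int, total: int, floor: float = 0.01) -> float:
    t = epoch / max(total, 1)
    if schedule == "step":
        return 1.0 if t < 0.6 else (0.1 if t < 0.85 else 0.01)
    if schedule == "cosine_restarts":
        cycle = 2 * (t * 2 - math.floor(t * 2)) if total > 1 else t
        return floor + (1 - floor) * 0.5 * (1 + math.cos(math.pi * min(cycle, 1.0)))
    # default: cosine annealing
    return floor + (1 - floor) * 0.5 * (1 + math.cos(math.pi * t))


def _set_temperature(model: DetectionModel, tau: float) -> None:
    for _, m in model.named_modules():
        if isinstance(m, DynamicConv2d):
            m.temperature = tau


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

def _prepare_batch(samples, size: int):
    imgs = np.stack([s[0] for s in samples])[:, None]  # (N,1,H,W)
    targets = []
    for _, anns in samples:
        t = np.array([[a.class_id, *a.box] for a in anns], dtype=np.float32)
        targets.append(t.reshape(-1, 5))
    return Tensor(imgs), targets


def evaluate(model: DetectionModel, val_data, conf_threshold: float = 0.25):
    per_image = []
    for img, anns in val_data:
        dets = predict(model, img, conf_threshold=conf_threshold)
        per_image.append((dets, anns))
    if not any(len(g) for _, g in per_image):
        return {"map50": 0.0, "map50_95": 0.0, "recall": 0.0, "precision": 0.0}
    summary = mean_average_precision(per_image)
    return {"map50": summary.map50, "map50_95": summary.map50_95,
            "recall": summary.recall, "precision": summary.precision}


def train(model: DetectionModel, dataset_dir, config: TrainConfig,
          log: Optional[Callable[[str], None]] = None,
          checkpoint_path=None) -> tuple[DetectionModel, list[dict]]:
    """SGD training with per-epoch validation and early stopping."""
    rng = np.random.default_rng(np.random.SeedSequence([101, config.seed]))
    train_data = load_split(dataset_dir, "train")
    val_data = load_split(dataset_dir, "val")
    params = model.parameters()
    opt = SGD(params, config.learning_rate, config.momentum, config.weight_decay)
    history: list[dict] = []
    best = {"map50": -1.0, "state": None, "epoch": -1}
    n = len(train_data)

    def sampler():
        img, anns = train_data[rng.integers(n)]
        return img, list(anns)

    for epoch in range(config.epochs):
        model.train()
        tau = max(1.0, config.tau_start
                  * (1 - epoch / max(1, config.epochs // 2)))
        _set_temperature(model, tau)
        opt.lr = config.learning_rate * lr_factor(config.lr_schedule, epoch,
                                                  config.epochs)
        if epoch < config.warmup_epochs:
            opt.lr *= (epoch + 1) / (config.warmup_epochs + 1)
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            samples = []
            for i in idx:
                img, anns = train_data[i]
                img, anns = augment(img, anns, config.augment, rng, sampler)
                samples.append((img, anns))
            x, targets = _prepare_batch(samples, config.input_size)
            preds = model(x)
            loss, parts = composite_detection_loss(
                preds, targets, model.nc, model.head.reg_max)
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}: {parts}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        model.eval()
        _set_temperature(model, 1.0)
        stats = evaluate(model, val_data, config.conf_threshold)
        rec = {"epoch": epoch, "loss": epoch_loss / max(n_batches, 1),
               "lr": opt.lr, **stats}
        history.append(rec)
        if log:
            log(f"epoch {epoch}: loss={rec['loss']:.4f} mAP50={rec['map50']:.3f}"
                f" recall={rec['recall']:.3f} lr={opt.lr:.5f}")
        if stats["map50"] > best["map50"]:
            best = {"map50": stats["map50"],
                    "state": {k: v.copy() for k, v in model.state_dict().items()},
                    "epoch": epoch}
        elif epoch - best["epoch"] >= config.patience:
            if log:
                log(f"early stop at epoch {epoch} (best {best['epoch']})")
            break
    if best["state"] is not None:
        model.load_state_dict(best["state"])
    model.eval()
    if checkpoint_path is not None:
        save_checkpoint(model, checkpoint_path)
    return model, history


def finetune(model: DetectionModel, dataset_dir,
             config: Optional[TrainConfig] = None,
             log: Optional[Callable[[str], None]] = None,
             checkpoint_path=None) -> tuple[DetectionModel, list[dict]]:
    """Post-prune fine-tuning: the same loop with the fine-tune defaults."""
    cfg = config or FINETUNE_DESK
    if cfg.epochs == 0:
        return model, []
    return train(model, dataset_dir, cfg, log, checkpoint_path)
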