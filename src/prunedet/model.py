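"""Detector graph assembly, profiling and inference post-processing.

The baseline graph follows the publicly documented YOLOv11 nano layer table
(stem, C3k2 stages, SPPF, C2PSA, PAN-style neck, decoupled anchor-free head
with distribution-focal box regression).  Variants:

* ``yolov11n_baseline`` — the unmodified nano graph.
* ``c_yolo``            — the two stem convolutions replaced by CSPP blocks.
* ``cd_yolo``           — additionally every C3k2 made dynamic (DCC).
* ``cdc_yolo``          — additionally one CPCA block on each of the three
                          feature streams feeding the detection head.
* ``tiny_cdc``          — cdc topology at width multiplier 0.125, single
                          input channel and reg_max 8, sized for CPU runs at
                          128 px.

Profiling counts exact weights and convolution multiply-accumulates on the
batch-norm-fused graph (FLOPs = 2 x MACs; activations, pooling and the
attention matmuls are not counted), the convention under which the published
nano baseline profiles at ~2.58 M parameters and ~6.3 GFLOPs at 640 px.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np

from .nn import (Tensor, cat, no_grad, MacCounter, mac_counting,
                 Module, ModuleList, Upsample2x)
from .blocks import (ConvBNAct, CSPP, C3k2, SPPF, C2PSA, CPCA, Detect)

VARIANTS = ("yolov11n_baseline", "c_yolo", "cd_yolo", "cdc_yolo", "tiny_cdc")

# Frozen module knobs, calibrated once against the published nano-scale
# parameter/GFLOP table and then fixed (see docs/methods.md).
DEFAULT_KNOBS = dict(
    dyn_kernels=3,        # kernel-bank size K of the dynamic convolutions
    cpca_reduction=4,     # channel-attention MLP reduction ratio r
    cspp_mid=(8, 8),      # CSPP branch width per stem stage (at width 0.25)
    cspp_hid=(14, 12),    # CSPP fuse width per stem stage (at width 0.25)
)


def make_divisible(x: float, divisor: int = 8) -> int:
    return max(divisor, int(round(x / divisor) * divisor))


@dataclasses.dataclass
class LayerSpec:
    index: int
    module: Module
    frm: object            # int or list of ints; -1 = previous layer
    kind: str
    c_out: int


class DetectionModel(Module):
    """Ordered layer graph with saved intermediate outputs (PAN wiring)."""

    def __init__(self, layers: list[LayerSpec], save: set[int], nc: int,
                 variant: str, img_size: int):
        super().__init__()
        self.layers = [spec.module for spec in layers]
        self.specs = layers
        self.save = save
        self.nc = nc
        self.variant = variant
        self.img_size = img_size

    def forward(self, x: Tensor, keep: Optional[set[int]] = None):
        outputs: dict[int, Tensor] = {}
        kept: dict[int, Tensor] = {}
        y = x
        for spec in self.specs:
            if isinstance(spec.frm, list):
                inp = [y if f == -1 else outputs[f] for f in spec.frm]
            else:
                inp = y if spec.frm == -1 else outputs[spec.frm]
            if spec.kind == "concat":
                y = cat(inp, axis=1)
            elif spec.kind == "detect":
                y = spec.module(inp)
            else:
                y = spec.module(inp)
            if spec.index in self.save:
                outputs[spec.index] = y
            if keep and spec.index in keep:
                kept[spec.index] = y
        if keep:
            return y, kept
        return y

    @property
    def head(self) -> Detect:
        return self.specs[-1].module

    def head_input_indices(self) -> list[int]:
        return list(self.specs[-1].frm)


def build_model(variant: str, nc: int = 1, width: Optional[float] = None,
                in_ch: Optional[int] = None, img_size: Optional[int] = None,
                seed: int = 0, knobs: Optional[dict] = None) -> DetectionModel:
    """Assemble a detection graph for one of the named variants."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    kn = dict(DEFAULT_KNOBS)
    if knobs:
        kn.update(knobs)
    tiny = variant == "tiny_cdc"
    w = width if width is not None else (0.125 if tiny else 0.25)
    in_ch = in_ch if in_ch is not None else (1 if tiny else 3)
    img_size = img_size if img_size is not None else (128 if tiny else 640)
    reg_max = 8 if tiny else 16
    rng = np.random.default_rng(seed)

    use_cspp = variant != "yolov11n_baseline"
    dynamic = variant in ("cd_yolo", "cdc_yolo", "tiny_cdc")
    use_cpca = variant in ("cdc_yolo", "tiny_cdc")
    K = kn["dyn_kernels"]

    def ch(c):
        return make_divisible(min(c, 1024) * w, 8 if w >= 0.25 else 4)

    c1, c2, c3, c4, c5 = ch(64), ch(128), ch(256), ch(512), ch(1024)

    # CSPP internal widths scale with the width multiplier
    scale = w / 0.25
    mids = tuple(max(4, round(m * scale)) for m in kn["cspp_mid"])
    hids = tuple(max(4, round(h * scale)) for h in kn["cspp_hid"])

    layers: list[LayerSpec] = []

    def add(module, frm, kind, c_out):
        layers.append(LayerSpec(len(layers), module, frm, kind, c_out))
        return len(layers) - 1

    if use_cspp:
        add(CSPP(in_ch, c1, mids[0], hids[0], rng=rng), -1, "cspp", c1)       # 0 P1/2
        add(CSPP(c1, c2, mids[1], hids[1], rng=rng), -1, "cspp", c2)          # 1 P2/4
    else:
        add(ConvBNAct(in_ch, c1, 3, 2, rng=rng), -1, "conv", c1)              # 0 P1/2
        add(ConvBNAct(c1, c2, 3, 2, rng=rng), -1, "conv", c2)                 # 1 P2/4
    add(C3k2(c2, c3, 1, c3k=False, e=0.25, dynamic=dynamic, K=K, rng=rng), -1, "c3k2", c3)   # 2
    add(ConvBNAct(c3, c3, 3, 2, rng=rng), -1, "conv", c3)                     # 3 P3/8
    add(C3k2(c3, c4, 1, c3k=False, e=0.25, dynamic=dynamic, K=K, rng=rng), -1, "c3k2", c4)   # 4
    add(ConvBNAct(c4, c4, 3, 2, rng=rng), -1, "conv", c4)                     # 5 P4/16
    add(C3k2(c4, c4, 1, c3k=True, dynamic=dynamic, K=K, rng=rng), -1, "c3k2", c4)            # 6
    add(ConvBNAct(c4, c5, 3, 2, rng=rng), -1, "conv", c5)                     # 7 P5/32
    add(C3k2(c5, c5, 1, c3k=True, dynamic=dynamic, K=K, rng=rng), -1, "c3k2", c5)            # 8
    add(SPPF(c5, c5, 5, rng=rng), -1, "sppf", c5)                             # 9
    add(C2PSA(c5, c5, 1, rng=rng), -1, "c2psa", c5)                           # 10

    add(Upsample2x(), -1, "upsample", c5)                                     # 11
    add(None, [-1, 6], "concat", c5 + c4)                                     # 12
    add(C3k2(c5 + c4, c4, 1, c3k=False, dynamic=dynamic, K=K, rng=rng), -1, "c3k2", c4)      # 13
    add(Upsample2x(), -1, "upsample", c4)                                     # 14
    add(None, [-1, 4], "concat", c4 + c4)                                     # 15
    add(C3k2(c4 + c4, c3, 1, c3k=False, dynamic=dynamic, K=K, rng=rng), -1, "c3k2", c3)      # 16 P3
    add(ConvBNAct(c3, c3, 3, 2, rng=rng), -1, "conv", c3)                     # 17
    add(None, [-1, 13], "concat", c3 + c4)                                    # 18
    add(C3k2(c3 + c4, c4, 1, c3k=False, dynamic=dynamic, K=K, rng=rng), -1, "c3k2", c4)      # 19 P4
    add(ConvBNAct(c4, c4, 3, 2, rng=rng), -1, "conv", c4)                     # 20
    add(None, [-1, 10], "concat", c4 + c5)                                    # 21
    add(C3k2(c4 + c5, c5, 1, c3k=True, dynamic=dynamic, K=K, rng=rng), -1, "c3k2", c5)       # 22 P5

    head_srcs = [16, 19, 22]
    head_chs = [c3, c4, c5]
    if use_cpca:
        r = kn["cpca_reduction"]
        new_srcs = []
        for src, c in zip(head_srcs, head_chs):
            new_srcs.append(add(CPCA(c, reduction=r, rng=rng), src, "cpca", c))
        head_srcs = new_srcs

    det = Detect(nc, head_chs, reg_max=reg_max, rng=rng)
    det.bias_init(img_size)
    add(det, head_srcs, "detect", 0)

    save = {6, 4, 13, 10, 16, 19, 22} | set(head_srcs)
    # fix up concat modules (they carry no module object)
    for spec in layers:
        if spec.module is None:
            spec.module = Upsample2x()  # placeholder, never called for concat
        if isinstance(spec.frm, list):
            spec.frm = [f if f != -1 else spec.index - 1 for f in spec.frm]
            for f in spec.frm:
                save.add(f)
    model = DetectionModel(layers, save, nc, variant, img_size)
    model.eval()
    return model


# ---------------------------------------------------------------------------
# Profiling
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class LayerProfile:
    index: int
    kind: str
    params: int
    macs: int


@dataclasses.dataclass
class ProfileReport:
    variant: str
    input_size: int
    total_params: int                # batch-norm-fused weight count
    raw_params: int                  # unfused (separate BN scale/shift)
    flops: float                     # 2 x MACs, absolute count
    per_layer: list[LayerProfile]

    @property
    def params_m(self) -> float:
        return self.total_params / 1e6

    @property
    def gflops(self) -> float:
        return self.flops / 1e9

    def summary(self) -> str:
        lines = [f"variant {self.variant} @ {self.input_size}px:"
                 f" {self.params_m:.2f}M params, {self.gflops:.1f} GFLOPs"]
        for lp in self.per_layer:
            lines.append(f"  layer {lp.index:2d} {lp.kind:8s}"
                         f" params={lp.params:9d} macs={lp.macs:12d}")
        return "\n".join(lines)


def profile_model(model: DetectionModel, input_size: Optional[int] = None,
                  in_ch: Optional[int] = None) -> ProfileReport:
    """Exact weight count and fused-graph conv MACs at the given input size."""
    input_size = input_size or model.img_size
    if input_size % 32:
        raise ValueError("input size must be divisible by 32")
    if in_ch is None:
        in_ch = model.specs[0].module.cv1.conv.c_in if model.specs[0].kind == "cspp" \
            else model.specs[0].module.conv.c_in
    model.eval()
    x = Tensor(np.zeros((1, in_ch, input_size, input_size), dtype=np.float32))
    counter = MacCounter()
    per_layer: list[LayerProfile] = []
    with no_grad(), mac_counting(counter):
        outputs: dict[int, Tensor] = {}
        y = x
        for spec in model.specs:
            before = counter.macs
            if isinstance(spec.frm, list):
                inp = [y if f == -1 else outputs[f] for f in spec.frm]
            else:
                inp = y if spec.frm == -1 else outputs[spec.frm]
            y = cat(inp, axis=1) if spec.kind == "concat" else spec.module(inp)
            if spec.index in model.save:
                outputs[spec.index] = y
            params = spec.module.num_params() if spec.kind != "concat" else 0
            per_layer.append(LayerProfile(spec.index, spec.kind, params,
                                          counter.macs - before))
    from .nn import BatchNorm2d
    raw_params = model.num_params()
    assert raw_params == sum(lp.params for lp in per_layer)
    # folding BN into the preceding convolution replaces its scale/shift pair
    # by a single bias vector, so the fused count drops by one value/channel
    bn_channels = sum(m.c for _, m in model.named_modules()
                      if isinstance(m, BatchNorm2d))
    return ProfileReport(model.variant, input_size, raw_params - bn_channels,
                         raw_params, 2.0 * counter.macs, per_layer)


# ---------------------------------------------------------------------------
# Inference post-processing
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Detection:
    box: tuple[float, float, float, float]   # x1, y1, x2, y2 pixels
    score: float
    class_id: int


def box_iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU of (N,4) and (M,4) xyxy boxes."""
    area_a = np.maximum(a[:, 2] - a[:, 0], 0) * np.maximum(a[:, 3] - a[:, 1], 0)
    area_b = np.maximum(b[:, 2] - b[:, 0], 0) * np.maximum(b[:, 3] - b[:, 1], 0)
    lt = np.maximum(a[:, None, :2], b[None, :, :2])
    rb = np.minimum(a[:, None, 2:], b[None, :, 2:])
    wh = np.clip(rb - lt, 0, None)
    inter = wh[..., 0] * wh[..., 1]
    union = area_a[:, None] + area_b[None, :] - inter
    out = np.zeros_like(inter)
    np.divide(inter, union, out=out, where=union > 0)
    return out


def nms(boxes: np.ndarray, scores: np.ndarray, iou_threshold: float) -> list[int]:
    """Greedy non-maximum suppression; returns kept indices, score-descending."""
    order = np.argsort(-scores, kind="stable")
    keep: list[int] = []
    suppressed = np.zeros(len(scores), dtype=bool)
    for i in order:
        if suppressed[i]:
            continue
        keep.append(int(i))
        if not suppressed.all():
            ious = box_iou_matrix(boxes[i: i + 1], boxes)[0]
            suppressed |= (ious > iou_threshold)
            suppressed[i] = True
    return keep


def letterbox_params(h: int, w: int, size: int) -> tuple[float, float, float]:
    """Scale and x/y offsets mapping original -> letterboxed coordinates."""
    r = size / max(h, w)
    nh, nw = round(h * r), round(w * r)
    return r, (size - nw) / 2, (size - nh) / 2


def letterbox_image(img: np.ndarray, size: int) -> np.ndarray:
    """Resize (nearest) and center-pad a 2-D or CHW image to size x size."""
    if img.ndim == 2:
        img = img[None]
    c, h, w = img.shape
    r, dx, dy = letterbox_params(h, w, size)
    nh, nw = round(h * r), round(w * r)
    yi = np.clip((np.arange(nh) + 0.5) / r - 0.5, 0, h - 1).round().astype(int)
    xi = np.clip((np.arange(nw) + 0.5) / r - 0.5, 0, w - 1).round().astype(int)
    resized = img[:, yi][:, :, xi]
    out = np.full((c, size, size), 0.0, dtype=np.float32)
    y0, x0 = int(round(dy)), int(round(dx))
    out[:, y0:y0 + nh, x0:x0 + nw] = resized
    return out


def decode_predictions(raw: list[Tensor], nc: int, reg_max: int,
                       strides: Sequence[int] = (8, 16, 32)):
    """Raw per-scale maps -> (boxes_xyxy, scores) in network input pixels."""
    from .blocks import DFL
    dfl = DFL(reg_max)
    all_boxes, all_scores = [], []
    for p, s in zip(raw, strides):
        n, cch, h, w = p.data.shape
        a = h * w
        flat = p.data.reshape(n, cch, a)
        box = dfl(Tensor(flat[:, : 4 * reg_max])).data          # (N,4,A) distances
        cls_logits = np.clip(flat[:, 4 * reg_max:], -37.0, 37.0)
        cls = 1.0 / (1.0 + np.exp(-cls_logits))                  # (N,nc,A)
        gy, gx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        cx = (gx.reshape(-1) + 0.5) * s
        cy = (gy.reshape(-1) + 0.5) * s
        x1 = cx - box[:, 0] * s
        y1 = cy - box[:, 1] * s
        x2 = cx + box[:, 2] * s
        y2 = cy + box[:, 3] * s
        all_boxes.append(np.stack([x1, y1, x2, y2], axis=2))     # (N,A,4)
        all_scores.append(cls.transpose(0, 2, 1))                # (N,A,nc)
    return np.concatenate(all_boxes, axis=1), np.concatenate(all_scores, axis=1)


def predict(model: DetectionModel, image: np.ndarray,
            conf_threshold: float = 0.25, nms_iou: float = 0.45,
            max_det: int = 100) -> list[Detection]:
    """Run inference on one grayscale or CHW image; boxes in original pixels."""
    img = np.asarray(image, dtype=np.float32)
    if img.size == 0:
        raise ValueError("empty image")
    if img.ndim == 2:
        img = img[None]
    h, w = img.shape[1], img.shape[2]
    size = model.img_size
    x = letterbox_image(img, size)[None]
    model.eval()
    with no_grad():
        raw = model(Tensor(x))
    reg_max = model.head.reg_max
    boxes, scores = decode_predictions(raw, model.nc, reg_max)
    boxes, scores = boxes[0], scores[0]
    r, dx, dy = letterbox_params(h, w, size)
    out: list[Detection] = []
    for c in range(model.nc):
        sc = scores[:, c]
        mask = sc >= conf_threshold
        if not mask.any():
            continue
        b, s = boxes[mask], sc[mask]
        keep = nms(b, s, nms_iou)
        for i in keep[:max_det]:
            x1 = np.clip((b[i, 0] - dx) / r, 0, w)
            y1 = np.clip((b[i, 1] - dy) / r, 0, h)
            x2 = np.clip((b[i, 2] - dx) / r, 0, w)
            y2 = np.clip((b[i, 3] - dy) / r, 0, h)
            if x2 > x1 and y2 > y1:
                out.append(Detection((float(x1), float(y1), float(x2), float(y2)),
                                     float(s[i]), c))
    out.sort(key=lambda d: -d.score)
    return out


def save_detections(path, records: list[tuple[str, list[Detection]]]) -> None:
    """Write predictions as tab-separated records: image, class, score, box."""
    lines = ["image\tclass\tscore\tx1\ty1\tx2\ty2"]
    for image_id, dets in records:
        for d in dets:
            x1, y1, x2, y2 = d.box
            lines.append(f"{image_id}\t{d.class_id}\t{d.score:.6f}"
                         f"\t{x1:.2f}\t{y1:.2f}\t{x2:.2f}\t{y2:.2f}")
    from pathlib import Path
    Path(path).write_text("\n".join(lines) + "\n")


def save_checkpoint(model: DetectionModel, path) -> None:
    import json
    meta = dict(variant=model.variant, nc=model.nc, img_size=model.img_size)
    sd = {f"param/{k}": v for k, v in model.state_dict().items()}
    np.savez(path, __meta__=np.array([json.dumps(meta)]), **sd)


def load_checkpoint(path, **overrides) -> DetectionModel:
    import json
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["__meta__"][0]))
    meta.update(overrides)
    model = build_model(meta["variant"], nc=meta["nc"], img_size=meta["img_size"])
    sd = {k[len("param/"):]: data[k] for k in data.files if k.startswith("param/")}
    model.load_state_dict(sd)
    return model
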