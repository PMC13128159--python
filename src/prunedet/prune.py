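"""Progressive hybrid structured pruning (PHPS).

The strategy removes whole channels in small steps until a global sparsity
target ``s`` is reached.  While a channel space's own sparsity ``SL`` is
below the threshold ``SC`` the L1 criterion ranks channels by the absolute
sum of their producing weights (coarse, magnitude-driven); once ``SL >= SC``
the group criterion ranks them by the sum of squares over *all* structurally
coupled weights — producer rows, pass-through depthwise kernels, batch-norm
scale/shift and every consumer column — so late pruning respects local
structural dependency.  Fine-tuning happens exactly once, after the loop.

Channel spaces ("groups" in the dependency sense) are registered explicitly
per block type: bottleneck hiddens, residual-coupled C3k hiddens, SPPF and
stem hiddens, attention MLP hiddens and detection-head hidden convolutions.
Trunk channels that cross stage boundaries and the head's output
convolutions are never pruned.  Surgery is physical: weight tensors are
sliced on producer and consumer axes, so the pruned model runs as-is.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Optional, Sequence

import numpy as np

from .nn import Conv2d, BatchNorm2d
from .blocks import (ConvBNAct, DynConvBNAct, DynamicConv2d, Bottleneck, C3k,
                     C3k2, SPPF, CSPP, C2PSA, CPCA, Detect)
from .model import DetectionModel


# ---------------------------------------------------------------------------
# Channel-space registry
# ---------------------------------------------------------------------------

# axis kinds: how a module participates in a channel space
#   conv_out / conv_in : Conv2d output rows / input columns
#   dyn_out  / dyn_in  : DynamicConv2d kernel-bank axes (dyn_in also slices
#                        the attention FC1 columns)
#   bn                 : BatchNorm2d channel entries
#   dw                 : depthwise Conv2d whose in==out==groups follow the space

@dataclasses.dataclass
class AxisRef:
    module: object
    kind: str
    layout: list[str]          # ordered group ids along this axis


@dataclasses.dataclass
class Group:
    gid: str
    size: int
    orig_size: int
    min_channels: int = 4

    @property
    def sparsity(self) -> float:
        return 1.0 - self.size / self.orig_size


class PruneGraph:
    """Explicit channel-dependency registry over a model's modules."""

    def __init__(self):
        self.groups: dict[str, Group] = {}
        self.axes: list[AxisRef] = []
        self.attr_hooks: list[tuple[object, str, str]] = []  # (obj, attr, gid)

    def add_group(self, gid: str, size: int, min_channels: int = 4) -> str:
        if gid in self.groups:
            raise ValueError(f"duplicate group {gid}")
        self.groups[gid] = Group(gid, size, size, min_channels)
        return gid

    def add_axis(self, module, kind: str, layout: Sequence[str]) -> None:
        layout = [g for g in layout]
        self.axes.append(AxisRef(module, kind, layout))

    def add_attr_hook(self, obj, attr: str, gid: str) -> None:
        self.attr_hooks.append((obj, attr, gid))

    # -- helpers -----------------------------------------------------------
    def _absolute(self, layout: Sequence[str], gid: str,
                  idx: np.ndarray) -> np.ndarray:
        out = []
        base = 0
        for g in layout:
            if g == gid:
                out.append(base + idx)
            base += self.groups[g].size if g in self.groups else int(g.split(":")[1])
        return np.concatenate(out) if out else np.zeros(0, dtype=int)

    def member_axes(self, gid: str):
        return [ax for ax in self.axes if gid in ax.layout]

    # -- importance --------------------------------------------------------
    def l1_importance(self, gid: str) -> np.ndarray:
        """Per-channel sum of |producer weights| plus |BN scale|."""
        g = self.groups[gid]
        score = np.zeros(g.size)
        for ax in self.member_axes(gid):
            m = ax.module
            if ax.kind in ("conv_out", "dw"):
                w = np.abs(m.weight.data).sum(axis=(1, 2, 3))
                score += self._gather(ax, gid, w)
            elif ax.kind == "dyn_out":
                w = np.abs(m.weight.data).sum(axis=(0, 2, 3, 4))
                score += self._gather(ax, gid, w)
            elif ax.kind == "bn":
                score += self._gather(ax, gid, np.abs(m.weight.data))
        return score

    def group_importance(self, gid: str) -> np.ndarray:
        """Per-channel sum of squared weights over every coupled member."""
        g = self.groups[gid]
        score = np.zeros(g.size)
        for ax in self.member_axes(gid):
            m = ax.module
            if ax.kind in ("conv_out", "dw"):
                score += self._gather(ax, gid, (m.weight.data ** 2).sum(axis=(1, 2, 3)))
                if getattr(m, "bias", None) is not None:
                    score += self._gather(ax, gid, m.bias.data ** 2)
            elif ax.kind == "conv_in":
                score += self._gather(ax, gid, (m.weight.data ** 2).sum(axis=(0, 2, 3)))
            elif ax.kind == "dyn_out":
                score += self._gather(ax, gid, (m.weight.data ** 2).sum(axis=(0, 2, 3, 4)))
            elif ax.kind == "dyn_in":
                score += self._gather(ax, gid, (m.weight.data ** 2).sum(axis=(0, 1, 3, 4)))
                score += self._gather(ax, gid, (m.fc1_w.data ** 2).sum(axis=0))
            elif ax.kind == "bn":
                score += self._gather(ax, gid, m.weight.data ** 2 + m.bias.data ** 2)
        return score

    def _gather(self, ax: AxisRef, gid: str, per_channel: np.ndarray) -> np.ndarray:
        """Sum the slices of ``per_channel`` belonging to ``gid``."""
        g = self.groups[gid]
        out = np.zeros(g.size)
        base = 0
        for name in ax.layout:
            sz = self.groups[name].size if name in self.groups else int(name.split(":")[1])
            if name == gid:
                out += per_channel[base:base + sz]
            base += sz
        return out

    def total_channels(self) -> tuple[int, int]:
        cur = sum(g.size for g in self.groups.values())
        orig = sum(g.orig_size for g in self.groups.values())
        return cur, orig

    def global_sparsity(self) -> float:
        cur, orig = self.total_channels()
        return 1.0 - cur / orig

    # -- surgery -----------------------------------------------------------
    def apply(self, plan: "PruningPlan") -> None:
        """Physically remove the planned channels; recomputed per call."""
        removals = {gid: np.asarray(sorted(idx), dtype=int)
                    for gid, idx in plan.removals.items() if len(idx)}
        for gid, idx in removals.items():
            g = self.groups[gid]
            if len(idx) >= g.size:
                raise ValueError(f"plan would empty group {gid}")
            if idx.min() < 0 or idx.max() >= g.size:
                raise ValueError(f"plan indices out of range for {gid}")
        # compute absolute indices per axis with pre-step sizes
        axis_removals: list[tuple[AxisRef, np.ndarray]] = []
        for ax in self.axes:
            cols = [self._absolute(ax.layout, gid, idx)
                    for gid, idx in removals.items() if gid in ax.layout]
            if cols:
                allc = np.unique(np.concatenate(cols))
                axis_removals.append((ax, allc))
        for ax, cols in axis_removals:
            self._slice_axis(ax, cols)
        for gid, idx in removals.items():
            self.groups[gid].size -= len(idx)
        for obj, attr, gid in self.attr_hooks:
            setattr(obj, attr, self.groups[gid].size)

    @staticmethod
    def _slice_axis(ax: AxisRef, cols: np.ndarray) -> None:
        m = ax.module
        if ax.kind == "conv_out":
            m.weight.data = np.delete(m.weight.data, cols, axis=0)
            if m.bias is not None:
                m.bias.data = np.delete(m.bias.data, cols, axis=0)
            m.c_out -= len(cols)
        elif ax.kind == "conv_in":
            m.weight.data = np.delete(m.weight.data, cols, axis=1)
            m.c_in -= len(cols)
        elif ax.kind == "dw":
            m.weight.data = np.delete(m.weight.data, cols, axis=0)
            if m.bias is not None:
                m.bias.data = np.delete(m.bias.data, cols, axis=0)
            m.c_in -= len(cols)
            m.c_out -= len(cols)
            m.groups -= len(cols)
        elif ax.kind == "dyn_out":
            m.weight.data = np.delete(m.weight.data, cols, axis=1)
            m.c2 -= len(cols)
        elif ax.kind == "dyn_in":
            m.weight.data = np.delete(m.weight.data, cols, axis=2)
            m.fc1_w.data = np.delete(m.fc1_w.data, cols, axis=1)
            m.c1 -= len(cols)
        elif ax.kind == "bn":
            m.weight.data = np.delete(m.weight.data, cols, axis=0)
            m.bias.data = np.delete(m.bias.data, cols, axis=0)
            m.running_mean = np.delete(m.running_mean, cols, axis=0)
            m.running_var = np.delete(m.running_var, cols, axis=0)
            m.c -= len(cols)
        else:  # pragma: no cover
            raise ValueError(f"unknown axis kind {ax.kind}")


@dataclasses.dataclass
class PruningPlan:
    removals: dict[str, list[int]]
    criteria: dict[str, str]

    def is_empty(self) -> bool:
        return not any(self.removals.values())

    def n_channels(self) -> int:
        return sum(len(v) for v in self.removals.values())


@dataclasses.dataclass
class PruneConfig:
    s: float = 0.3          # overall target sparsity
    sc: float = 0.3         # per-layer threshold switching L1 -> group
    m: float = 0.05         # step pruning ratio
    seed: int = 0
    min_channels: int = 4

    def __post_init__(self):
        if not (0 <= self.s < 1):
            raise ValueError("target sparsity s must be in [0, 1)")
        if not (0 <= self.sc <= 1):
            raise ValueError("threshold SC must be in [0, 1]")
        if not (0 < self.m <= 0.5):
            raise ValueError("step ratio M must be in (0, 0.5]")


# ---------------------------------------------------------------------------
# Free-function operation surface
# ---------------------------------------------------------------------------

def channel_importance_l1(layer) -> np.ndarray:
    """L1 importance of a convolution layer's output channels.

    Accepts a Conv2d, a ConvBNAct (convolution + its batch-norm scale
    magnitude) or a DynConvBNAct; anything without an output-channel weight
    axis raises TypeError (the not-prunable marker).
    """
    if isinstance(layer, ConvBNAct):
        return (np.abs(layer.conv.weight.data).sum(axis=(1, 2, 3))
                + np.abs(layer.bn.weight.data))
    if isinstance(layer, DynConvBNAct):
        return (np.abs(layer.conv.weight.data).sum(axis=(0, 2, 3, 4))
                + np.abs(layer.bn.weight.data))
    if isinstance(layer, Conv2d):
        return np.abs(layer.weight.data).sum(axis=(1, 2, 3))
    raise TypeError(f"layer {type(layer).__name__} has no prunable channel axis")


def group_importance(weights: Sequence[np.ndarray]) -> float:
    """Sum of squared weights over all members of one coupled group."""
    arrays = [np.asarray(w) for w in weights]
    if not arrays or sum(a.size for a in arrays) == 0:
        raise ValueError("empty group")
    return float(sum((a.astype(np.float64) ** 2).sum() for a in arrays))


def plan_prune_step(graph: PruneGraph, config: PruneConfig,
                    min_one: bool = True) -> PruningPlan:
    """One pass of the staged criterion over every prunable channel space."""
    removals: dict[str, list[int]] = {}
    criteria: dict[str, str] = {}
    for gid, g in graph.groups.items():
        use_l1 = g.sparsity < config.sc
        criteria[gid] = "l1" if use_l1 else "group"
        k = int(np.floor(config.m * g.size))
        if k == 0 and min_one and g.size > g.min_channels:
            k = 1
        k = min(k, g.size - g.min_channels)
        if k <= 0:
            removals[gid] = []
            continue
        score = graph.l1_importance(gid) if use_l1 else graph.group_importance(gid)
        order = np.argsort(score, kind="stable")
        removals[gid] = sorted(int(i) for i in order[:k])
    return PruningPlan(removals, criteria)


def apply_prune(graph: PruneGraph, plan: PruningPlan) -> None:
    graph.apply(plan)


@dataclasses.dataclass
class StepRecord:
    step: int
    gid: str
    criterion: str
    sl_before: float
    removed: list[int]


def phps_run(model, config: PruneConfig,
             finetune_hook: Optional[Callable] = None,
             graph: Optional[PruneGraph] = None,
             criterion: str = "hybrid") -> tuple[object, list[StepRecord]]:
    """Progressive pruning loop; fine-tunes exactly once after the loop.

    ``criterion``: "hybrid" (the staged SC switch), "l1_only", "group_only"
    or "random" (seeded uniform ranking).  Returns (model, step trace).
    """
    if graph is None:
        graph = build_prune_graph(model)
    rng = np.random.default_rng(config.seed)
    trace: list[StepRecord] = []
    step = 0
    while graph.global_sparsity() < config.s:
        cfg = config
        if criterion == "l1_only":
            cfg = dataclasses.replace(config, sc=1.0)
        elif criterion == "group_only":
            cfg = dataclasses.replace(config, sc=0.0)
        sl_before = {gid: g.sparsity for gid, g in graph.groups.items()}
        if criterion == "random":
            plan = _random_plan(graph, config, rng)
        else:
            plan = plan_prune_step(graph, cfg)
        if plan.is_empty():
            raise RuntimeError(
                "pruning cannot progress: every layer is at its channel floor "
                f"(S={graph.global_sparsity():.3f} < s={config.s})")
        graph.apply(plan)
        for gid in sorted(plan.removals):
            if plan.removals[gid]:
                trace.append(StepRecord(step, gid,
                                        "random" if criterion == "random"
                                        else plan.criteria[gid],
                                        sl_before[gid], plan.removals[gid]))
        step += 1
    if finetune_hook is not None:
        finetune_hook(model)
    return model, trace


def _random_plan(graph: PruneGraph, config: PruneConfig,
                 rng: np.random.Generator) -> PruningPlan:
    removals, criteria = {}, {}
    for gid, g in graph.groups.items():
        criteria[gid] = "random"
        k = int(np.floor(config.m * g.size))
        if k == 0 and g.size > g.min_channels:
            k = 1
        k = min(k, g.size - g.min_channels)
        removals[gid] = sorted(rng.choice(g.size, size=k, replace=False).tolist()) \
            if k > 0 else []
    return PruningPlan(removals, criteria)


def baseline_criteria(model, config: PruneConfig, kind: str,
                      finetune_hook: Optional[Callable] = None,
                      graph: Optional[PruneGraph] = None):
    """Single-criterion ablations of the pruning loop (L1 / group / random)."""
    if kind not in ("l1_only", "group_only", "random"):
        raise ValueError(f"unknown pruning criterion {kind!r}")
    return phps_run(model, config, finetune_hook, graph, criterion=kind)


def stability_report(checkpoint_path, dataset_dir, prune_config: PruneConfig,
                     seeds: Sequence[int], finetune_config=None,
                     criterion: str = "hybrid") -> dict:
    """Repeat prune+fine-tune from one checkpoint across seeds; report the
    sample SD of mAP_0.5 and mAP_0.5:0.95 (the repeat-seed stability
    protocol).  Returns per-seed metrics and the SD summary."""
    import dataclasses as _dc
    from .metrics import metric_sd
    from .model import load_checkpoint
    from .train import finetune as _finetune, evaluate as _evaluate, load_split

    val = load_split(dataset_dir, "val")
    rows = []
    for seed in seeds:
        model = load_checkpoint(checkpoint_path)
        cfg = _dc.replace(prune_config, seed=int(seed))
        hook = None
        if finetune_config is not None:
            fcfg = _dc.replace(finetune_config, seed=int(seed))
            hook = lambda m: _finetune(m, dataset_dir, fcfg)  # noqa: E731
        if criterion == "hybrid":
            model, _ = phps_run(model, cfg, finetune_hook=hook)
        else:
            model, _ = baseline_criteria(model, cfg, criterion,
                                         finetune_hook=hook)
        stats = _evaluate(model, val)
        rows.append({"seed": int(seed), **stats})
    sd_map50 = metric_sd([r["map50"] for r in rows])
    sd_map5095 = metric_sd([r["map50_95"] for r in rows])
    lines = ["method  SD(mAP_0.5) x1e-3  SD(mAP_0.5:0.95) x1e-3",
             f"{criterion:7s} {sd_map50 * 1e3:18.2f} {sd_map5095 * 1e3:22.2f}"]
    return {"criterion": criterion, "runs": rows,
            "sd_map50": sd_map50, "sd_map50_95": sd_map5095,
            "report": "\n".join(lines)}


def trace_lines(trace: Sequence[StepRecord]) -> str:
    return "\n".join(
        f"step={r.step} layer={r.gid} criterion={r.criterion} "
        f"SL={r.sl_before:.4f} removed={','.join(map(str, r.removed))}"
        for r in trace) + ("\n" if trace else "")


# ---------------------------------------------------------------------------
# Dependency-graph construction for the detection model
# ---------------------------------------------------------------------------

def _reg_convbn(graph, m, gid_out):
    graph.add_axis(m.conv, "conv_out", [gid_out] if isinstance(gid_out, str) else gid_out)
    graph.add_axis(m.bn, "bn", [gid_out] if isinstance(gid_out, str) else gid_out)


def _reg_in(graph, m, layout):
    if isinstance(m, ConvBNAct):
        graph.add_axis(m.conv, "conv_in", layout)
    elif isinstance(m, DynConvBNAct):
        graph.add_axis(m.conv, "dyn_in", layout)
    elif isinstance(m, Conv2d):
        graph.add_axis(m, "conv_in", layout)
    else:  # pragma: no cover
        raise TypeError(type(m))


def _reg_out(graph, m, layout):
    layout = [layout] if isinstance(layout, str) else layout
    if isinstance(m, ConvBNAct):
        graph.add_axis(m.conv, "conv_out", layout)
        graph.add_axis(m.bn, "bn", layout)
    elif isinstance(m, DynConvBNAct):
        graph.add_axis(m.conv, "dyn_out", layout)
        graph.add_axis(m.bn, "bn", layout)
    else:  # pragma: no cover
        raise TypeError(type(m))


def _fixed(n: int) -> str:
    """Layout entry for a non-prunable (trunk) span of n channels."""
    return f"fixed:{n}"


def _register_bottleneck(graph, name, b: Bottleneck, in_layout, out_layout,
                         min_ch: int):
    """Bottleneck cv1 -> hidden -> cv2; hidden is its own channel space."""
    hid = graph.add_group(f"{name}.hidden", b.cv1.conv.c_out
                          if isinstance(b.cv1, ConvBNAct) else b.cv1.conv.c2,
                          min_ch)
    _reg_in(graph, b.cv1, in_layout)
    _reg_out(graph, b.cv1, hid)
    _reg_in(graph, b.cv2, [hid])
    _reg_out(graph, b.cv2, out_layout)


def _register_c3k(graph, name, m: C3k, in_layout, out_layout, min_ch: int):
    c_ = m.cv1.conv.c_out
    gc = graph.add_group(f"{name}.c", c_, min_ch)
    _reg_in(graph, m.cv1, in_layout)
    _reg_out(graph, m.cv1, gc)
    _reg_in(graph, m.cv2, in_layout)
    _reg_out(graph, m.cv2, gc)
    for i, b in enumerate(m.m):
        # e=1.0 residual bottlenecks: outputs coupled to gc
        _register_bottleneck(graph, f"{name}.b{i}", b, [gc], gc, min_ch)
    _reg_in(graph, m.cv3, [gc, gc])
    _reg_out(graph, m.cv3, out_layout)


def _register_c3k2(graph, name, blk: C3k2, min_ch: int):
    c = blk.c
    ga = graph.add_group(f"{name}.a", c, min_ch)
    gb = graph.add_group(f"{name}.b", c, min_ch)
    graph.add_attr_hook(blk, "c_a", ga)
    graph.add_attr_hook(blk, "c_b", gb)
    _reg_out(graph, blk.cv1, [ga, gb])
    cv2_layout = [ga, gb]
    prev = gb
    for i, m in enumerate(blk.m):
        if isinstance(m, C3k):
            gm = graph.add_group(f"{name}.m{i}", c, min_ch)
            _register_c3k(graph, f"{name}.m{i}", m, [prev], gm, min_ch)
            prev = gm
        else:  # Bottleneck with e=0.5; shortcut couples output to its input
            if m.add:
                _register_bottleneck(graph, f"{name}.m{i}", m, [prev], prev, min_ch)
            else:
                gm = graph.add_group(f"{name}.m{i}", c, min_ch)
                _register_bottleneck(graph, f"{name}.m{i}", m, [prev], gm, min_ch)
                prev = gm
        cv2_layout.append(prev)
    _reg_in(graph, blk.cv2, cv2_layout)
    # cv2 output is trunk: not registered


def _register_sppf(graph, name, m: SPPF, min_ch: int):
    gs = graph.add_group(f"{name}.hidden", m.cv1.conv.c_out, min_ch)
    _reg_out(graph, m.cv1, gs)
    _reg_in(graph, m.cv2, [gs, gs, gs, gs])


def _register_cspp(graph, name, m: CSPP, min_ch: int):
    gm = graph.add_group(f"{name}.mid", m.cv1.conv.c_out, min_ch)
    graph.add_attr_hook(m, "c_mid", gm)
    _reg_out(graph, m.cv1, gm)
    _reg_in(graph, m.cv2, [gm, gm])
    gh = graph.add_group(f"{name}.hid", m.cv2.conv.c_out, min_ch)
    _reg_out(graph, m.cv2, gh)
    _reg_in(graph, m.cv3, [gh])


def _register_c2psa(graph, name, m: C2PSA, min_ch: int):
    for i, blk in enumerate(m.m):
        c = blk.ffn[0].conv.c_in
        gf = graph.add_group(f"{name}.psa{i}.ffn", blk.ffn[0].conv.c_out, min_ch)
        _reg_in(graph, blk.ffn[0], [_fixed(c)])
        _reg_out(graph, blk.ffn[0], gf)
        _reg_in(graph, blk.ffn[1], [gf])


def _register_cpca(graph, name, m: CPCA, min_ch: int):
    gh = graph.add_group(f"{name}.mlp", m.mlp1.c_out, max(1, min_ch // 2))
    graph.add_axis(m.mlp1, "conv_out", [gh])
    graph.add_axis(m.mlp2, "conv_in", [gh])


def _register_detect(graph, name, d: Detect, min_ch: int):
    for i in range(d.nl):
        seq = d.cv2[i]
        g1 = graph.add_group(f"{name}.cv2_{i}.h1", seq[0].conv.c_out, min_ch)
        g2 = graph.add_group(f"{name}.cv2_{i}.h2", seq[1].conv.c_out, min_ch)
        _reg_out(graph, seq[0], g1)
        _reg_in(graph, seq[1], [g1])
        _reg_out(graph, seq[1], g2)
        graph.add_axis(seq[2], "conv_in", [g2])
        # cv3: [DWConv(x,x), Conv(x,c3), DWConv(c3,c3), Conv(c3,c3), Conv2d(c3,nc)]
        seq3 = d.cv3[i]
        ga = graph.add_group(f"{name}.cv3_{i}.h1", seq3[1].conv.c_out, min_ch)
        gb = graph.add_group(f"{name}.cv3_{i}.h2", seq3[3].conv.c_out, min_ch)
        _reg_out(graph, seq3[1], ga)
        graph.add_axis(seq3[2].conv, "dw", [ga])
        graph.add_axis(seq3[2].bn, "bn", [ga])
        _reg_in(graph, seq3[3], [ga])
        _reg_out(graph, seq3[3], gb)
        graph.add_axis(seq3[4], "conv_in", [gb])


def build_prune_graph(model: DetectionModel,
                      min_channels: int = 4) -> PruneGraph:
    """Register every prunable channel space of a detection model."""
    graph = PruneGraph()
    for spec in model.specs:
        name = f"layer{spec.index}"
        m = spec.module
        if spec.kind == "c3k2":
            _register_c3k2(graph, name, m, min_channels)
        elif spec.kind == "sppf":
            _register_sppf(graph, name, m, min_channels)
        elif spec.kind == "cspp":
            _register_cspp(graph, name, m, min_channels)
        elif spec.kind == "c2psa":
            _register_c2psa(graph, name, m, min_channels)
        elif spec.kind == "cpca":
            _register_cpca(graph, name, m, min_channels)
        elif spec.kind == "detect":
            _register_detect(graph, name, m, min_channels)
        # plain convs, upsample, concat: trunk, not prunable
    return graph
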