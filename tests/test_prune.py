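"""PHPS pruning: importance oracles, step planning against a standalone
re-implementation of the staged pseudocode, surgery soundness, endpoint
equivalences and the single-fine-tune contract."""

import dataclasses

import numpy as np
import pytest

from prunedet.nn import Tensor, no_grad, Conv2d, BatchNorm2d
from prunedet.blocks import ConvBNAct
from prunedet.model import build_model, profile_model
from prunedet.prune import (PruneGraph, PruneConfig, PruningPlan,
                            plan_prune_step, apply_prune, phps_run,
                            baseline_criteria, build_prune_graph,
                            channel_importance_l1, group_importance,
                            trace_lines)

rng = np.random.default_rng(21)


# ---------------------------------------------------------------------------
# Toy 2-layer CNN with an explicit dependency graph
# ---------------------------------------------------------------------------

class ToyCNN:
    """conv1 (1->8) -> conv2 (8->6) -> head (6->2); two prunable spaces."""

    def __init__(self, seed=0):
        r = np.random.default_rng(seed)
        self.conv1 = ConvBNAct(1, 8, 3, rng=r)
        self.conv2 = ConvBNAct(8, 6, 3, rng=r)
        self.head = Conv2d(6, 2, 1, rng=r)

    def graph(self):
        g = PruneGraph()
        g.add_group("conv1", self.conv1.conv.c_out, min_channels=2)
        g.add_group("conv2", self.conv2.conv.c_out, min_channels=2)
        g.add_axis(self.conv1.conv, "conv_out", ["conv1"])
        g.add_axis(self.conv1.bn, "bn", ["conv1"])
        g.add_axis(self.conv2.conv, "conv_in", ["conv1"])
        g.add_axis(self.conv2.conv, "conv_out", ["conv2"])
        g.add_axis(self.conv2.bn, "bn", ["conv2"])
        g.add_axis(self.head, "conv_in", ["conv2"])
        return g

    def forward(self, x):
        with no_grad():
            return self.head(self.conv2(self.conv1(Tensor(x)))).data


def standalone_phps_oracle(weights, bn_scales, bn_biases, cons_weights,
                           s, sc, m, min_ch):
    """From-scratch staged pruning trace on per-layer weight arrays.

    ``weights[l]``: producing conv weight (C_out, ...); ``cons_weights[l]``:
    the consumer weight tensor whose axis-1 columns follow layer ``l`` (the
    consumer of the last layer never loses rows).  The group criterion sums
    squares over the *surviving* coupled weights, so consumer columns are
    restricted to the consumer's own alive rows.  Returns the ordered list
    of (step, layer, removed relative indices).
    """
    sizes = [w.shape[0] for w in weights]
    orig = list(sizes)
    alive = [list(range(n)) for n in sizes]
    trace = []
    step = 0
    while 1 - sum(sizes) / sum(orig) < s:
        any_removed = False
        for l in range(len(weights)):
            sl = 1 - sizes[l] / orig[l]
            k = int(np.floor(m * sizes[l]))
            if k == 0 and sizes[l] > min_ch:
                k = 1
            k = min(k, sizes[l] - min_ch)
            if k <= 0:
                continue
            wl = weights[l][alive[l]]
            if sl < sc:
                score = np.abs(wl).sum(axis=tuple(range(1, wl.ndim))) \
                    + np.abs(bn_scales[l][alive[l]])
            else:
                cons = cons_weights[l]
                rows = alive[l + 1] if l + 1 < len(weights) else range(cons.shape[0])
                cols = (cons[list(rows)][:, alive[l]] ** 2).sum(
                    axis=tuple(i for i in range(cons.ndim) if i != 1))
                score = (wl ** 2).sum(axis=tuple(range(1, wl.ndim))) \
                    + bn_scales[l][alive[l]] ** 2 + bn_biases[l][alive[l]] ** 2 \
                    + cols
            order = np.argsort(score, kind="stable")[:k]
            removed = sorted(int(i) for i in order)
            trace.append((step, l, removed))
            for i in sorted(removed, reverse=True):
                del alive[l][i]
            sizes[l] -= k
            any_removed = True
        if not any_removed:
            raise RuntimeError("stuck")
        step += 1
    return trace


class TestImportance:
    def test_zero_channel_ranked_first(self):
        conv = ConvBNAct(3, 4, 3, rng=np.random.default_rng(0))
        conv.conv.weight.data[2] = 0
        conv.bn.weight.data[2] = 0
        scores = channel_importance_l1(conv)
        assert scores[2] == 0 and np.argsort(scores)[0] == 2

    def test_sign_flip_invariance(self):
        conv = ConvBNAct(3, 4, 3, rng=np.random.default_rng(1))
        s1 = channel_importance_l1(conv)
        conv.conv.weight.data *= -1
        s2 = channel_importance_l1(conv)
        np.testing.assert_allclose(s1, s2)

    def test_ranking_matches_independent_sort(self):
        conv = Conv2d(2, 4, 3, bias=False, rng=np.random.default_rng(2))
        conv.weight.data = rng.normal(size=(4, 2, 3, 3)).astype(np.float32)
        scores = channel_importance_l1(conv)
        ref = np.abs(conv.weight.data).sum(axis=(1, 2, 3))
        assert np.argsort(scores).tolist() == np.argsort(ref).tolist()

    def test_unprunable_layer_raises(self):
        with pytest.raises(TypeError):
            channel_importance_l1(object())

    def test_group_importance_direct_arithmetic(self):
        g1 = group_importance([np.array([0.1, 0.2])])
        g2 = group_importance([np.array([0.05]), np.array([0.3])])
        assert g1 == pytest.approx(0.05)
        assert g2 == pytest.approx(0.0925)
        assert g1 < g2  # ascending order picks the first

    def test_group_importance_monotone_in_magnitude(self):
        base = [np.array([0.1, -0.2, 0.3])]
        bigger = [np.array([0.1, -0.25, 0.3])]
        assert group_importance(bigger) > group_importance(base)

    def test_group_importance_empty_raises(self):
        with pytest.raises(ValueError):
            group_importance([])


class TestPlanStep:
    def test_zero_ratio_floor_disabled_gives_empty_plan(self):
        toy = ToyCNN()
        g = toy.graph()
        cfg = PruneConfig(s=0.5, sc=0.3, m=0.05)
        plan = plan_prune_step(g, cfg, min_one=False)
        assert plan.is_empty()

    def test_fresh_model_uses_l1_everywhere(self):
        toy = ToyCNN()
        g = toy.graph()
        plan = plan_prune_step(g, PruneConfig(s=0.5, sc=0.3, m=0.25))
        assert set(plan.criteria.values()) == {"l1"}

    def test_trace_matches_standalone_pseudocode_oracle(self):
        toy = ToyCNN(seed=5)
        g = toy.graph()
        cfg = PruneConfig(s=0.5, sc=0.3, m=0.25)
        _, trace = phps_run(toy, cfg, graph=g)
        # oracle over the same two channel spaces
        toy2 = ToyCNN(seed=5)
        ref = standalone_phps_oracle(
            [toy2.conv1.conv.weight.data, toy2.conv2.conv.weight.data],
            [toy2.conv1.bn.weight.data, toy2.conv2.bn.weight.data],
            [toy2.conv1.bn.bias.data, toy2.conv2.bn.bias.data],
            [toy2.conv2.conv.weight.data, toy2.head.weight.data],
            s=0.5, sc=0.3, m=0.25, min_ch=2)
        got = [(r.step, {"conv1": 0, "conv2": 1}[r.gid], r.removed)
               for r in trace]
        assert sorted(got) == sorted(ref)

    def test_criterion_switch_replay(self):
        """criterion == l1 iff SL < SC at step start, over the whole log."""
        toy = ToyCNN(seed=6)
        g = toy.graph()
        cfg = PruneConfig(s=0.6, sc=0.25, m=0.2)
        _, trace = phps_run(toy, cfg, graph=g)
        for r in trace:
            assert (r.criterion == "l1") == (r.sl_before < cfg.sc)


class TestSurgery:
    def test_empty_plan_is_identity(self):
        toy = ToyCNN(seed=7)
        g = toy.graph()
        x = rng.normal(size=(1, 1, 8, 8)).astype(np.float32)
        y0 = toy.forward(x)
        apply_prune(g, PruningPlan({"conv1": [], "conv2": []}, {}))
        np.testing.assert_allclose(toy.forward(x), y0)

    def test_null_channel_removal_preserves_outputs(self):
        toy = ToyCNN(seed=8)
        toy.conv1.conv.weight.data[3] = 0
        toy.conv1.bn.weight.data[3] = 0
        toy.conv1.bn.bias.data[3] = 0
        toy.conv1.bn.running_mean[3] = 0
        toy.conv1.bn.running_var[3] = 1
        x = rng.normal(size=(2, 1, 8, 8)).astype(np.float32)
        y0 = toy.forward(x)
        g = toy.graph()
        apply_prune(g, PruningPlan({"conv1": [3], "conv2": []}, {}))
        np.testing.assert_allclose(toy.forward(x), y0, atol=1e-5)

    def test_masking_oracle_and_param_count(self):
        """Pruning equals zero-masking the removed channels when those
        channels are null, and the parameter count drops by a hand count."""
        toy = ToyCNN(seed=9)
        for i in (1, 4):
            toy.conv1.conv.weight.data[i] = 0
            toy.conv1.bn.weight.data[i] = 0
            toy.conv1.bn.bias.data[i] = 0
            toy.conv1.bn.running_mean[i] = 0
            toy.conv1.bn.running_var[i] = 1
        n0 = sum(p.numel() for m in (toy.conv1, toy.conv2)
                 for p in m.parameters()) + toy.head.weight.numel() \
            + toy.head.bias.numel()
        x = rng.normal(size=(1, 1, 6, 6)).astype(np.float32)
        y_masked = toy.forward(x)          # channels already null
        g = toy.graph()
        apply_prune(g, PruningPlan({"conv1": [1, 4], "conv2": []}, {}))
        np.testing.assert_allclose(toy.forward(x), y_masked, atol=1e-5)
        n1 = sum(p.numel() for m in (toy.conv1, toy.conv2)
                 for p in m.parameters()) + toy.head.weight.numel() \
            + toy.head.bias.numel()
        # removed per channel: conv1 row (1*3*3) + bn (2) + conv2 column (6*3*3)
        assert n0 - n1 == 2 * (9 + 2 + 54)

    def test_plan_emptying_a_group_rejected(self):
        toy = ToyCNN(seed=10)
        g = toy.graph()
        with pytest.raises(ValueError):
            apply_prune(g, PruningPlan({"conv1": list(range(8))}, {}))


@pytest.fixture(scope="module")
def pruned_tiny():
    model = build_model("tiny_cdc", seed=2)
    graph = build_prune_graph(model)
    calls = []
    cfg = PruneConfig(s=0.3, sc=0.3, m=0.1, seed=0)
    model, trace = phps_run(model, cfg, finetune_hook=lambda m: calls.append(1),
                            graph=graph)
    return model, graph, trace, calls, cfg


class TestFullModelPruning:
    def test_sparsity_lands_in_band(self, pruned_tiny):
        _, graph, _, _, cfg = pruned_tiny
        s_final = graph.global_sparsity()
        assert cfg.s <= s_final < cfg.s + cfg.m + 0.05

    def test_single_finetune_invocation(self, pruned_tiny):
        _, _, _, calls, _ = pruned_tiny
        assert calls == [1]

    def test_monotone_sparsity_trace(self, pruned_tiny):
        _, _, trace, _, _ = pruned_tiny
        steps = sorted({r.step for r in trace})
        assert steps == list(range(len(steps)))
        for st in steps:
            assert any(r.removed for r in trace if r.step == st)

    def test_forward_shape_at_two_sizes(self, pruned_tiny):
        model, _, _, _, _ = pruned_tiny
        for size in (128, 64):
            x = Tensor(np.zeros((1, 1, size, size), dtype=np.float32))
            with no_grad():
                outs = model(x)
            assert [o.data.shape[2] for o in outs] == [size // 8, size // 16,
                                                       size // 32]

    def test_param_count_strictly_decreases(self, pruned_tiny):
        model, _, _, _, _ = pruned_tiny
        fresh = build_model("tiny_cdc", seed=2)
        assert model.num_params() < fresh.num_params()

    def test_trace_log_format(self, pruned_tiny):
        _, _, trace, _, _ = pruned_tiny
        text = trace_lines(trace)
        assert "criterion=" in text and "step=0" in text


class TestEndpoints:
    def test_s_zero_returns_untouched_but_finetunes_once(self):
        toy = ToyCNN(seed=11)
        g = toy.graph()
        x = rng.normal(size=(1, 1, 8, 8)).astype(np.float32)
        y0 = toy.forward(x)
        calls = []
        _, trace = phps_run(toy, PruneConfig(s=0.0, m=0.25),
                            finetune_hook=lambda m: calls.append(1), graph=g)
        assert trace == [] and calls == [1]
        np.testing.assert_allclose(toy.forward(x), y0)

    def test_l1_only_equals_hybrid_with_sc_one(self):
        t1, t2 = ToyCNN(seed=12), ToyCNN(seed=12)
        _, tr1 = baseline_criteria(t1, PruneConfig(s=0.5, sc=0.3, m=0.25),
                                   "l1_only", graph=t1.graph())
        _, tr2 = phps_run(t2, PruneConfig(s=0.5, sc=1.0, m=0.25),
                          graph=t2.graph())
        assert [(r.step, r.gid, r.removed) for r in tr1] == \
            [(r.step, r.gid, r.removed) for r in tr2]

    def test_group_only_equals_hybrid_with_sc_zero(self):
        t1, t2 = ToyCNN(seed=13), ToyCNN(seed=13)
        _, tr1 = baseline_criteria(t1, PruneConfig(s=0.5, sc=0.7, m=0.25),
                                   "group_only", graph=t1.graph())
        _, tr2 = phps_run(t2, PruneConfig(s=0.5, sc=0.0, m=0.25),
                          graph=t2.graph())
        assert [(r.step, r.gid, r.removed) for r in tr1] == \
            [(r.step, r.gid, r.removed) for r in tr2]

    def test_random_criterion_reproducible(self):
        t1, t2 = ToyCNN(seed=14), ToyCNN(seed=14)
        _, tr1 = baseline_criteria(t1, PruneConfig(s=0.4, m=0.25, seed=5),
                                   "random", graph=t1.graph())
        _, tr2 = baseline_criteria(t2, PruneConfig(s=0.4, m=0.25, seed=5),
                                   "random", graph=t2.graph())
        assert [(r.step, r.gid, r.removed) for r in tr1] == \
            [(r.step, r.gid, r.removed) for r in tr2]

    def test_unknown_criterion_rejected(self):
        toy = ToyCNN()
        with pytest.raises(ValueError):
            baseline_criteria(toy, PruneConfig(), "lamp", graph=toy.graph())


def test_prune_config_validation():
    with pytest.raises(ValueError):
        PruneConfig(s=1.0)
    with pytest.raises(ValueError):
        PruneConfig(m=0.0)
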