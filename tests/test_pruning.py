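"""BN-scale structured pruning: thresholding, plans, surgery, iteration."""

import copy

import numpy as np
import pytest

from rootarm import nn
from rootarm.backbone import TinySegNet
from rootarm.complexity import ArchitectureSpec, ConvLayer, report
from rootarm.pruning import (
    BNLayerState,
    PruneConfig,
    PruningPlan,
    apply_plan,
    bn_forward,
    build_pruning_plan,
    compute_threshold,
    iterative_prune,
    sparsity_penalty,
)
from rootarm.train import TrainSettings, train_segmentation


class TestBNForward:
    def test_input_at_mean_returns_beta(self):
        st = BNLayerState(gamma=np.array([3.0]), beta=np.array([0.5]),
                          mu=np.array([1.7]), sigma2=np.array([2.0]))
        assert bn_forward(np.array([1.7]), st) == pytest.approx([0.5])

    def test_hand_arithmetic(self):
        st = BNLayerState(gamma=np.array([2.0]), beta=np.array([0.5]),
                          mu=np.array([1.0]), sigma2=np.array([4.0]), eps=0.0)
        assert bn_forward(np.array([3.0]), st) == pytest.approx([2.5])

    def test_zero_gamma_is_constant_beta(self, rng):
        st = BNLayerState(gamma=np.array([0.0]), beta=np.array([0.9]),
                          mu=np.array([0.0]), sigma2=np.array([1.0]))
        assert np.allclose(bn_forward(rng.normal(size=7), st), 0.9)

    def test_degenerate_denominator_rejected(self):
        with pytest.raises(ValueError):
            BNLayerState(gamma=np.array([1.0]), beta=np.array([0.0]),
                         mu=np.array([0.0]), sigma2=np.array([0.0]), eps=0.0)


class TestSparsityPenalty:
    def test_hand_example(self):
        assert sparsity_penalty([np.array([0.5, -1.5])], 0.01) == pytest.approx(0.02)

    def test_zero_lambda_and_zero_gamma(self):
        assert sparsity_penalty([np.array([1.0, 2.0])], 0.0) == 0.0
        assert sparsity_penalty([np.zeros(5)], 0.3) == 0.0

    def test_loss_identity_on_fixed_toy_batch(self, small_scenes):
        """Sparsity-training loss equals segmentation loss plus the exact
        L1 term, asserted on one fixed batch."""
        from rootarm.train import scenes_to_tensors

        net = TinySegNet(rng_seed=5)
        x, y = scenes_to_tensors(small_scenes[:2])
        acts, _ = net.forward(x, train=True, update_bn_stats=False)
        seg, _ = net.segmentation_loss(acts["head"], y)
        lam = 1e-3
        gammas = [net.params[n]["gamma"] for n in
                  ("enc1_bn", "enc2_bn", "dec_bn")]
        expected = seg + lam * sum(np.abs(g).sum() for g in gammas)
        assert seg + sparsity_penalty(gammas, lam) == pytest.approx(expected)


class TestThreshold:
    def test_order_statistics_example(self):
        g = np.arange(0.1, 1.05, 0.1)  # 0.1 .. 1.0
        thr = compute_threshold(g, 0.3)
        assert 0.3 < thr <= 0.4
        assert (np.abs(g) < thr).sum() == 3

    def test_tiny_ratio_prunes_nothing(self):
        g = np.array([0.2, 0.4, 0.9])
        thr = compute_threshold(g, 1e-9)
        assert (np.abs(g) < thr).sum() == 0

    def test_all_equal_gammas_are_kept(self):
        g = np.full(8, 0.3)
        thr = compute_threshold(g, 0.5)
        assert (np.abs(g) < thr).sum() == 0

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            compute_threshold(np.array([]), 0.1)


class TestPlan:
    def test_threshold_below_min_gives_all_keep(self):
        net = TinySegNet(rng_seed=0)
        plan = build_pruning_plan(net, 0.0, PruneConfig())
        assert all(m.all() for m in plan.keep_masks.values())

    def test_zero_gamma_channel_dropped_and_consumer_sliced(self):
        net = TinySegNet(rng_seed=0)
        net.params["enc1_bn"]["gamma"][2] = 0.0
        plan = build_pruning_plan(net, 1e-9, PruneConfig())
        assert not plan.keep_masks["enc1_bn"][2]
        pruned = apply_plan(net, plan)
        c1 = pruned.params["enc1_conv"]["W"].shape[0]
        assert c1 == 15
        # consumer (dec conv through the concat) loses the same channel
        assert pruned.params["dec_conv"]["W"].shape[1] == 15 + 32

    def test_protected_layer_with_tiny_gamma_untouched(self):
        net = TinySegNet(rng_seed=0)
        cfg = PruneConfig(protected_layers=frozenset({"head", "enc2_conv"}))
        net.params["enc2_bn"]["gamma"][:] = 1e-9
        plan = build_pruning_plan(net, 0.5, cfg)
        assert plan.keep_masks["enc2_bn"].all()

    def test_never_empties_a_layer(self, caplog):
        net = TinySegNet(rng_seed=0)
        net.params["enc2_bn"]["gamma"][:] = 1e-9
        plan = build_pruning_plan(net, 0.5, PruneConfig())
        assert plan.keep_masks["enc2_bn"].sum() == 1

    def test_plan_json_roundtrippable_rle(self, tmp_path):
        plan = PruningPlan(
            keep_masks={"bn": np.array([True, True, False, True])},
            threshold=0.25,
        )
        path = tmp_path / "plan.json"
        plan.to_json(path)
        import json

        doc = json.loads(path.read_text())
        assert doc["keep_masks"]["bn"] == "2,1,1"
        assert doc["threshold"] == 0.25


class _AddSkipNet:
    """Two parallel conv branches summed element-wise, for coupling tests."""

    def __init__(self, rng_seed=0):
        rng = np.random.default_rng(rng_seed)
        self.nodes = [
            {"name": "input", "kind": "input"},
            {"name": "a_conv", "kind": "conv", "inputs": ["input"], "k": 3},
            {"name": "a_bn", "kind": "bn", "inputs": ["a_conv"]},
            {"name": "a", "kind": "relu", "inputs": ["a_bn"]},
            {"name": "b_conv", "kind": "conv", "inputs": ["input"], "k": 3},
            {"name": "b_bn", "kind": "bn", "inputs": ["b_conv"]},
            {"name": "b", "kind": "relu", "inputs": ["b_bn"]},
            {"name": "sum", "kind": "add", "inputs": ["a", "b"]},
            {"name": "head", "kind": "conv", "inputs": ["sum"], "k": 1},
        ]
        self.params = {
            "a_conv": nn.init_conv(rng, 3, 6, 3),
            "a_bn": nn.init_bn(6),
            "b_conv": nn.init_conv(rng, 3, 6, 3),
            "b_bn": nn.init_bn(6),
            "head": nn.init_conv(rng, 6, 2, 1, bias=True),
        }

    def graph_description(self, input_hw=(8, 8)):
        h, w = input_hw
        ca = self.params["a_conv"]["W"].shape[0]
        spec = ArchitectureSpec("addskip", [
            ConvLayer("a_conv", 3, ca, 3, 1, h, w, has_bn=True),
            ConvLayer("b_conv", 3, ca, 3, 1, h, w, has_bn=True),
            ConvLayer("head", ca, 2, 1, 1, h, w, has_bias=True, has_bn=False),
        ])
        info = {
            "nodes": self.nodes,
            "bn_of_conv": {"a_conv": "a_bn", "b_conv": "b_bn"},
            "protected": {"head"},
            "input_hw": input_hw,
        }
        return spec, info

    def forward(self, x, train=False, update_bn_stats=None):
        return nn.graph_forward(self.nodes, self.params, x, train=train,
                                update_bn_stats=update_bn_stats)


class TestCoupling:
    def test_add_coupled_branches_share_union_keep_mask(self):
        net = _AddSkipNet()
        net.params["a_bn"]["gamma"][:] = [0.0, 1, 1, 0.0, 1, 1]
        net.params["b_bn"]["gamma"][:] = [1, 0.0, 1, 0.0, 1, 1]
        plan = build_pruning_plan(net, 1e-9, PruneConfig())
        # union: channel 3 is the only one dropped by both branches
        expected = np.array([True, True, True, False, True, True])
        assert np.array_equal(plan.keep_masks["a_bn"], expected)
        assert np.array_equal(plan.keep_masks["b_bn"], expected)
        pruned = apply_plan(net, plan)
        assert pruned.params["a_conv"]["W"].shape[0] == 5
        assert pruned.params["head"]["W"].shape[1] == 5


class TestApplyPlan:
    def test_all_keep_is_bit_identical(self, rng):
        net = TinySegNet(rng_seed=1)
        plan = build_pruning_plan(net, 0.0, PruneConfig())
        pruned = apply_plan(net, plan)
        x = rng.normal(size=(1, 3, 16, 16))
        a, _ = net.forward(x)
        b, _ = pruned.forward(x)
        assert np.array_equal(a["head"], b["head"])

    def test_zero_gamma_zero_beta_channels_are_lossless(self, rng):
        net = TinySegNet(rng_seed=2)
        for bn, ch in (("enc1_bn", [1, 5]), ("enc2_bn", [0, 8])):
            net.params[bn]["gamma"][ch] = 0.0
            net.params[bn]["beta"][ch] = 0.0
        plan = build_pruning_plan(net, 1e-9, PruneConfig())
        pruned = apply_plan(net, plan)
        for _ in range(100):
            x = rng.normal(size=(1, 3, 12, 12))
            a, _ = net.forward(x)
            b, _ = pruned.forward(x)
            assert np.abs(a["head"] - b["head"]).max() < 1e-6

    def test_half_layer_prune_matches_analytic_param_delta(self):
        net = TinySegNet(rng_seed=3)
        keep = np.ones(32, dtype=bool)
        keep[:16] = False  # drop half of enc2
        plan = PruningPlan(keep_masks={
            "enc1_bn": np.ones(16, dtype=bool),
            "enc2_bn": keep,
            "dec_bn": np.ones(16, dtype=bool),
        }, threshold=0.0)
        pruned = apply_plan(net, plan)
        spec_b, _ = net.graph_description((64, 64))
        spec_a, _ = pruned.graph_description((64, 64))
        delta = report(spec_b).params_total - report(spec_a).params_total
        # enc2 conv rows (+BN) and dec conv input columns
        expected = 16 * (16 * 9 + 2) + 16 * 9 * 16
        assert delta == expected
        assert report(spec_a).params_total == pruned.param_count()

    def test_plan_model_mismatch_rejected(self):
        net = TinySegNet(rng_seed=0)
        plan = PruningPlan(keep_masks={"nope_bn": np.ones(4, dtype=bool)},
                           threshold=0.1)
        with pytest.raises(ValueError):
            apply_plan(net, plan)


class TestSparsityPressure:
    def test_l1_training_shrinks_median_gamma(self, small_scenes):
        base = TinySegNet(rng_seed=9)
        sparse = copy.deepcopy(base)
        train_segmentation(base, small_scenes[:6],
                           TrainSettings(epochs=4, rng_seed=1))
        train_segmentation(sparse, small_scenes[:6],
                           TrainSettings(epochs=4, rng_seed=1,
                                         sparsity_lambda=5e-3))
        def med(m):
            return np.median(np.abs(np.concatenate(
                [m.params[b]["gamma"] for b in ("enc1_bn", "enc2_bn", "dec_bn")]
            )))
        assert med(sparse) < med(base)


class TestIterativePrune:
    def test_two_iterations_monotone_and_keep_fraction(self, small_scenes,
                                                       trained_net):
        model = copy.deepcopy(trained_net)
        cfg = PruneConfig(iterations=2, ratio_per_iter=0.1,
                          sparse_epochs=2, finetune_epochs=2)
        models, rows = iterative_prune(model, small_scenes[:6], cfg,
                                       settings=TrainSettings(rng_seed=0))
        params = [r.params_m for r in rows]
        flops = [r.flops_g for r in rows]
        assert params[2] < params[1] < params[0]
        assert all(a >= b for a, b in zip(flops, flops[1:]))
        # cumulative keep fraction of prunable channels >= 0.9^2
        kept = sum(models[-1].params[b]["gamma"].size
                   for b in ("enc1_bn", "enc2_bn", "dec_bn"))
        assert kept >= 0.9**2 * 64
        # counted parameters match the analytic count after surgery
        spec, _ = models[-1].graph_description((96, 96))
        assert report(spec).params_total == models[-1].param_count()

    def test_zero_iterations_rejected(self):
        with pytest.raises(ValueError):
            PruneConfig(iterations=0)

    def test_bad_ratio_rejected(self):
        with pytest.raises(ValueError):
            PruneConfig(ratio_per_iter=1.5)
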