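"""BN arithmetic, the global prune threshold, mask construction and the
reconstruction equivalence oracle."""

import numpy as np
import pytest

from distilharvest import slimmer
from distilharvest.detnet import NetworkSpec, build_network
from distilharvest.slimmer import (BNState, align_union, bn_forward,
                                   build_masks, collect_gammas,
                                   global_threshold, prune_network,
                                   reconstruct, sparsity_penalty)


class TestBNForward:
    def test_identity_parameters(self):
        s = BNState(gamma=np.ones(1), beta=np.zeros(1), mu=np.zeros(1),
                    var=np.ones(1), eps=1e-12)
        x = np.array([0.3, -1.2, 4.0])
        assert np.allclose(bn_forward(x, s), x, atol=1e-6)

    def test_hand_computed_value(self):
        # x=2, mu=1, var=4, eps->0, gamma=3, beta=0.5: z=0.5, out=2.0
        s = BNState(gamma=np.array(3.0), beta=np.array(0.5),
                    mu=np.array(1.0), var=np.array(4.0), eps=1e-12)
        assert np.isclose(bn_forward(np.array(2.0), s), 2.0, atol=1e-6)

    def test_zero_gamma_collapses_to_beta(self):
        s = BNState(gamma=np.zeros(3), beta=np.array([1., 2., 3.]),
                    mu=np.zeros(3), var=np.ones(3))
        x = np.random.default_rng(0).standard_normal((2, 3, 4, 4))
        out = bn_forward(x, s)
        assert np.allclose(out, np.array([1, 2, 3]).reshape(1, 3, 1, 1)
                           * np.ones_like(out))

    def test_vector_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            BNState(gamma=np.ones(3), beta=np.ones(2), mu=np.ones(3),
                    var=np.ones(3)).validate()


class TestSparsityPenalty:
    def test_zero_lambda(self):
        assert float(sparsity_penalty([np.array([1.0, -2.0])], 0.0).data) == 0.0

    def test_hand_computed(self):
        pen = sparsity_penalty([np.array([1.0, -2.0, 0.5])], 0.1)
        assert np.isclose(float(pen.data), 0.35)

    def test_sign_invariance(self):
        g = np.array([0.3, -1.1, 2.0])
        assert np.isclose(float(sparsity_penalty([g], 0.2).data),
                          float(sparsity_penalty([-g], 0.2).data))


class TestGlobalThreshold:
    def test_fraction_zero_removes_nothing(self):
        g = np.array([0.5, 1.0, 2.0])
        thr = global_threshold(g, 0.0)
        assert (np.abs(g) >= thr).all()

    def test_eight_of_ten_removed(self):
        g = np.arange(1, 11) / 10.0
        thr = global_threshold(g, 0.8)
        assert (np.abs(g) < thr).sum() == 8

    def test_large_pool_fraction_accurate(self, rng):
        g = rng.uniform(0.01, 1.0, 1000)
        thr = global_threshold(g, 0.8)
        removed = (np.abs(g) < thr).sum()
        assert abs(removed - 800) <= 1   # at most one tie

    def test_empty_pool_raises(self):
        with pytest.raises(ValueError):
            global_threshold(np.array([]), 0.5)


class TestAlignUnion:
    def test_partner_union(self):
        keeps = {"a": np.array([True, False, True, False]),
                 "b": np.array([False, True, True, False])}
        out = align_union(keeps, [["a", "b"]])
        expect = np.array([True, True, True, False])
        assert np.array_equal(out["a"], expect)
        assert np.array_equal(out["b"], expect)

    def test_transitive_merge(self):
        keeps = {k: np.zeros(3, dtype=bool) for k in "abc"}
        keeps["a"][0] = keeps["b"][1] = keeps["c"][2] = True
        out = align_union(keeps, [["a", "b"], ["b", "c"]])
        assert all(out[k].all() for k in "abc")

    def test_protected_partner_pulls_group_full(self):
        keeps = {"a": np.array([True, False])}
        out = align_union(keeps, [["a", "stem_protected"]])
        assert out["a"].all()


def _randomized_net(role, rng, dropout=0.0):
    backbone = "cspdarknet" if role == "teacher" else "mobilenetv2"
    spec = NetworkSpec(role=role, backbone=backbone, input_side=96,
                       width_multiple=0.25, depth_multiple=0.33,
                       dropout=dropout)
    net = build_network(spec)
    for _name, u in net.bn_units():
        c = u.bn.channels
        u.bn.weight.data = rng.normal(0, 1, c).astype(np.float32)
        u.bn.bias.data = rng.normal(0, 0.5, c).astype(np.float32)
        u.bn.running_mean = rng.normal(0, 0.5, c).astype(np.float32)
        u.bn.running_var = rng.uniform(0.5, 2.0, c).astype(np.float32)
    net.eval()
    return net


class TestBuildMasks:
    def test_threshold_below_everything_keeps_all(self, rng):
        net = _randomized_net("student", rng)
        mask = build_masks(net, threshold=0.0)
        assert all(k.all() for k in mask.keeps.values())

    def test_floor_rule_keeps_argmax_channel(self, rng):
        net = _randomized_net("student", rng)
        name, unit = slimmer.prunable_units(net)[0]
        unit.bn.weight.data[:] = 0.01
        unit.bn.weight.data[2] = 0.02
        mask = build_masks(net, threshold=1e6)
        keep = mask.keeps[name]
        # the layer may sit in a residual union group; its own argmax survives
        assert keep[2]
        assert all(k.any() for k in mask.keeps.values())


class TestReconstruct:
    def test_all_true_mask_is_bit_identical(self, rng):
        net = _randomized_net("teacher", rng)
        mask = build_masks(net, threshold=0.0)
        pruned = reconstruct(net, mask)
        x = rng.random((1, 3, 96, 96)).astype(np.float32)
        for a, b in zip(net(x), pruned(x)):
            assert np.array_equal(a.data, b.data)

    @pytest.mark.parametrize("role", ["teacher", "student"])
    def test_equivalence_oracle_zeroed_channels(self, role, rng):
        """Zero the masked channels' (gamma, beta), prune, and compare
        outputs on random inputs: reconstruction must be lossless."""
        net = _randomized_net(role, rng)
        thr = global_threshold(collect_gammas(net), 0.5)
        mask = build_masks(net, thr, 0.5)
        for name, u in net.bn_units():
            if name in mask.keeps:
                removed = ~mask.keeps[name]
                u.bn.weight.data[removed] = 0.0
                u.bn.bias.data[removed] = 0.0
        pruned = reconstruct(net, mask)
        assert pruned.num_parameters() < net.num_parameters()
        for _ in range(4):
            x = rng.random((2, 3, 96, 96)).astype(np.float32)
            for a, b in zip(net(x), pruned(x)):
                scale = max(np.abs(a.data).max(), 1e-9)
                assert np.abs(a.data - b.data).max() / scale < 1e-5

    def test_param_count_monotone_in_fraction(self, rng):
        net = _randomized_net("student", rng)
        counts = [prune_network(net, f)[0].num_parameters()
                  for f in (0.0, 0.2, 0.4, 0.6, 0.8, 0.9)]
        assert counts[0] == net.num_parameters()
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert counts[-1] < counts[0]

    def test_removed_fraction_matches_target_on_tie_free_pool(self, rng):
        net = _randomized_net("student", rng)
        frac = 0.6
        thr = global_threshold(collect_gammas(net), frac)
        mask = build_masks(net, thr, frac)
        # exact up to the floor rule and union alignment, both of which only
        # put channels back
        assert mask.removed_fraction() <= frac + 1e-9
        assert mask.removed_fraction() > frac - 0.2

    def test_inconsistent_mask_names_layer(self, rng):
        net = _randomized_net("student", rng)
        mask = build_masks(net, 0.0)
        bad = dict(mask.keeps)
        first = next(iter(bad))
        bad[first] = bad[first][:-1]
        mask.keeps = bad
        with pytest.raises(ValueError, match=first.split(".")[0]):
            reconstruct(net, mask)


def test_sparsity_training_shrinks_gamma_distribution():
    """With lambda > 0 the lower tail of |gamma| contracts relative to an
    identically seeded run without the penalty."""
    from distilharvest.synthcarrot import CorpusSpec, build_corpus
    from distilharvest.training import images_to_batch, train_detector
    spec = CorpusSpec(per_class_count=4, image_side=96,
                      degrade_per_class=(0, 0), seed=3)
    corpus, _ = build_corpus(spec)
    X = images_to_batch(corpus[:12], 96)
    objs = [im.objects for im in corpus[:12]]
    q20 = {}
    for lam in (0.0, 5e-3):
        net = build_network(NetworkSpec(role="student", backbone="mobilenetv2",
                                        input_side=96, width_multiple=0.25,
                                        depth_multiple=0.33, dropout=0.0))
        train_detector(net, X, objs, epochs=4, batch=4, lr=1e-3, seed=5,
                       sparsity_lam=lam)
        q20[lam] = np.quantile(np.abs(collect_gammas(net)), 0.2)
    assert q20[5e-3] < q20[0.0]
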