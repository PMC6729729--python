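"""Boosting-loop tests: the per-step micro-oracles (sigmoid, bag vote,
weighted error, step size, weight update), the training loop, the
baseline, and the singleton-bag equivalence between the two."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import milboost as mb
from milboost.bags import Bag, BagWeights, Instance, MILDataset
from milboost.boosting import (
    MILBoost,
    TrainConfig,
    alpha_from_error,
    bag_hypothesis,
    sgn,
    sigmoid_prob,
    update_bag_weights,
    weighted_bag_error,
)
from conftest import random_dataset


class TestSigmoid:
    def test_midpoint(self):
        assert sigmoid_prob(0.0) == pytest.approx(0.5)

    def test_ln3_gives_three_quarters(self):
        assert sigmoid_prob(math.log(3)) == pytest.approx(0.75)

    def test_saturation_no_overflow(self):
        lo = sigmoid_prob(-1000.0)
        assert 0.0 < lo <= 1e-300
        assert sigmoid_prob(1000.0) == pytest.approx(1.0)


class TestBagHypothesis:
    def test_singleton_collapses_to_sign(self):
        assert bag_hypothesis([2.0]) == pytest.approx(1.0)
        assert bag_hypothesis([-0.3]) == pytest.approx(-1.0)

    def test_symmetric_pair(self):
        # p(ln 3) = 0.75, p(-ln 3) = 0.25 -> (0.75 - 0.25) / 1 = 0.5
        h = bag_hypothesis([math.log(3), -math.log(3)])
        assert h == pytest.approx(0.5)

    def test_unanimous_sign_is_exact(self):
        assert bag_hypothesis([0.2, 1.5, 3.0]) == pytest.approx(1.0)
        assert bag_hypothesis([-0.2, -1.5]) == pytest.approx(-1.0)

    def test_empty_bag_rejected(self):
        with pytest.raises(ValueError):
            bag_hypothesis([])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-20, 20), min_size=1, max_size=30))
    def test_bounded(self, confs):
        assert -1.0 <= bag_hypothesis(confs) <= 1.0


class TestWeightedError:
    def test_all_correct_zero(self):
        w = BagWeights(np.array([0.5, 0.5]))
        assert weighted_bag_error(w, [0.9, -0.9], [1, -1]) == 0.0

    def test_all_wrong_one(self):
        w = BagWeights(np.array([0.25, 0.75]))
        assert weighted_bag_error(w, [-0.9, 0.9], [1, -1]) == pytest.approx(1.0)

    def test_middle_bag_wrong(self):
        w = BagWeights(np.array([0.5, 0.3, 0.2]))
        eps = weighted_bag_error(w, [1.0, -1.0, -1.0], [1, 1, -1])
        assert eps == pytest.approx(0.3)

    def test_sgn_zero_counts_as_negative(self):
        w = BagWeights(np.array([1.0]))
        assert weighted_bag_error(w, [0.0], [1]) == pytest.approx(1.0)
        assert weighted_bag_error(w, [0.0], [-1]) == 0.0

    def test_misalignment_rejected(self):
        with pytest.raises(ValueError):
            weighted_bag_error(BagWeights(np.array([1.0])), [1.0, 1.0], [1, 1])


class TestAlpha:
    def test_point_one_gives_half_ln_nine(self):
        assert alpha_from_error(0.1) == pytest.approx(0.5 * math.log(9.0))

    def test_zero_clamped_finite(self):
        a = alpha_from_error(0.0, clamp=1e-10)
        assert a == pytest.approx(0.5 * math.log((1 - 1e-10) / 1e-10))
        assert math.isfinite(a)

    def test_half_rejected(self):
        with pytest.raises(ValueError):
            alpha_from_error(0.5)

    def test_boundary_limit_is_zero(self):
        # alpha -> 0 as eps -> 0.5 from below
        assert alpha_from_error(0.4999999) == pytest.approx(0.0, abs=1e-6)


class TestWeightUpdate:
    def test_all_correct_unchanged(self):
        w = BagWeights(np.array([0.3, 0.7]))
        out = update_bag_weights(w, 1.3, [0.9, -0.2], [1, -1])
        np.testing.assert_allclose(out.w, w.w, atol=1e-15)

    def test_single_wrong_bag_hand_value(self):
        # uniform pair, one wrong, alpha = 1/2 ln 9: e^{±alpha} = 3^{±1}... the
        # wrong bag ends at 3 / (3 + 1/3) = 0.9
        w = BagWeights(np.array([0.5, 0.5]))
        alpha = 0.5 * math.log(9.0)
        out = update_bag_weights(w, alpha, [-1.0, -1.0], [1, -1])
        assert out.w[0] == pytest.approx(0.9)
        assert out.w[1] == pytest.approx(0.1)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(0.01, 3.0))
    def test_normalized_and_direction(self, seed, alpha):
        rng = np.random.default_rng(seed)
        n = 10
        raw = rng.random(n) + 1e-6
        w = BagWeights(raw / raw.sum())
        preds = rng.normal(size=n)
        labels = rng.choice([-1, 1], size=n)
        out = update_bag_weights(w, alpha, preds, labels)
        assert abs(out.w.sum() - 1.0) < 1e-12
        wrong = sgn(preds) != labels
        if wrong.any() and (~wrong).any():
            # up-weighted relative to correct bags
            z = (w.w * np.exp(-alpha * sgn(preds) * labels)).sum()
            np.testing.assert_allclose(
                out.w[wrong], w.w[wrong] * math.exp(alpha) / z, rtol=1e-12
            )


class TestFit:
    def test_separable_training_error_reaches_zero(self):
        ds = mb.generate(mb.SyntheticConfig(
            n_pos_bags=8, n_neg_bags=24, dim=4, separation=6.0, seed=5,
            bag_size=(3, 6),
        ))
        res = mb.fit(ds, T=30, max_depth=8)
        assert min(e for e, _ in res.ensemble.history) < 0.05
        assert res.training_bag_error() == 0.0

    def test_t1_single_round(self, tiny_dataset):
        res = mb.fit(tiny_dataset, T=1)
        assert res.T == 1

    def test_single_class_rejected(self):
        ds = MILDataset([Bag("p", 1, [Instance([0.0])])])
        with pytest.raises(ValueError, match="positive and negative"):
            MILBoost(ds, TrainConfig())

    def test_deterministic(self):
        ds = mb.generate(mb.SyntheticConfig(n_pos_bags=5, n_neg_bags=15,
                                            dim=5, seed=2, bag_size=(2, 5)))
        r1 = mb.fit(ds, T=10, max_depth=4)
        r2 = mb.fit(ds, T=10, max_depth=4)
        assert r1.ensemble.to_dict() == r2.ensemble.to_dict()

    def test_weights_sum_to_one_every_round(self):
        """Drift of the bag-weight simplex constraint over a long run."""
        ds = mb.generate(mb.SyntheticConfig(
            n_pos_bags=10, n_neg_bags=30, dim=6, separation=1.0,
            bag_size=(3, 8), seed=9,
        ))
        from milboost.bags import init_bag_weights, reorganize_negatives
        from milboost.boosting import _bag_hypotheses
        from milboost.tree import fit_tree

        rds = reorganize_negatives(ds)
        weights = init_bag_weights(rds)
        y = rds.labels()
        sizes = np.array([len(b) for b in rds.bags])
        bag_index = np.repeat(np.arange(rds.n), sizes)
        X = rds.feature_matrix()
        y_inst = y[bag_index]
        for _ in range(50):
            tree = fit_tree((X, y_inst, (weights.w / sizes)[bag_index]),
                            max_depth=2)
            h_bag = _bag_hypotheses(tree.predict(X), bag_index, rds.n)
            eps = weighted_bag_error(weights, h_bag, y)
            if eps >= 0.5:
                break
            weights = update_bag_weights(
                weights, alpha_from_error(eps), h_bag, y
            )
            assert abs(weights.w.sum() - 1.0) <= 1e-12

    def test_epsilon_below_half_for_retained_rounds(self):
        ds = mb.generate(mb.SyntheticConfig(n_pos_bags=10, n_neg_bags=40,
                                            dim=8, seed=3))
        res = mb.fit(ds, T=40, max_depth=6)
        assert all(e < 0.5 for e, _ in res.ensemble.history)
        assert all(a > 0 for _, a in res.ensemble.history)


class TestBaseline:
    def test_t_zero_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(T=0)

    def test_pure_noise_instance_auc_near_half(self):
        ds = mb.generate(mb.SyntheticConfig(
            n_pos_bags=40, n_neg_bags=40, dim=5, separation=0.0, seed=21,
            bag_size=(5, 10),
        ))
        test = mb.generate(mb.SyntheticConfig(
            n_pos_bags=40, n_neg_bags=40, dim=5, separation=0.0, seed=22,
            bag_size=(5, 10),
        ))
        res = mb.fit_adaboost_baseline(ds, T=10, max_depth=3)
        scores = res.score_instances(test.feature_matrix())
        curve = mb.roc_auc(scores, test.instance_true_labels())
        assert curve.auc == pytest.approx(0.5, abs=0.05)

    def test_mode_recorded(self, tiny_dataset):
        res = mb.fit_adaboost_baseline(tiny_dataset, T=2)
        assert res.ensemble.mode == "adaboost_baseline"


class TestSingletonEquivalence:
    """With every bag a singleton, bag-level boosting reduces exactly to
    discrete AdaBoost on instances: same ε_t, α_t and predictions."""

    def _singleton_dataset(self, seed=13, n=60, d=4):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, d))
        y = np.where(X[:, 1] + 0.3 * rng.normal(size=n) > 0, 1, -1)
        if len(set(y)) == 1:
            y[0] = -y[0]
        return MILDataset([
            Bag(f"b{i}", int(y[i]), [Instance(X[i])]) for i in range(n)
        ])

    def test_round_by_round_identical(self):
        ds = self._singleton_dataset()
        cfg = dict(T=12, max_depth=2)
        mil = mb.fit(ds, **cfg)
        base = mb.fit_adaboost_baseline(ds, **cfg)
        assert mil.T == base.T
        for (e1, a1), (e2, a2) in zip(mil.ensemble.history,
                                      base.ensemble.history):
            assert e1 == pytest.approx(e2, abs=1e-12)
            assert a1 == pytest.approx(a2, abs=1e-12)
        X = ds.feature_matrix()
        np.testing.assert_allclose(
            mil.score_instances(X), base.score_instances(X), atol=1e-12
        )
        np.testing.assert_allclose(
            mil.score_bags(ds), base.score_bags(ds), atol=1e-12
        )


class TestScoring:
    def _fitted(self):
        ds = mb.generate(mb.SyntheticConfig(n_pos_bags=6, n_neg_bags=18,
                                            dim=4, seed=8, bag_size=(2, 6)))
        return ds, mb.fit(ds, T=5, max_depth=3)

    def test_single_round_is_alpha_times_tree(self):
        ds, _ = self._fitted()
        res = mb.fit(ds, T=1, max_depth=3)
        alpha, tree = res.ensemble.rounds[0]
        X = ds.feature_matrix()
        np.testing.assert_allclose(
            res.score_instances(X), alpha * tree.predict(X)
        )

    def test_score_linearity_in_rounds(self):
        ds, res = self._fitted()
        from milboost.boosting import EnsembleModel
        doubled = EnsembleModel(res.ensemble.rounds * 2, mode="mil",
                                d=res.ensemble.d)
        X = ds.feature_matrix()
        np.testing.assert_allclose(
            doubled.score_instances(X), 2 * res.score_instances(X), rtol=1e-12
        )

    def test_instance_scores_order_invariant(self):
        ds, res = self._fitted()
        X = ds.feature_matrix()
        perm = np.random.default_rng(0).permutation(X.shape[0])
        np.testing.assert_array_equal(
            res.score_instances(X)[perm], res.score_instances(X[perm])
        )

    def test_bag_score_bounded_by_alpha_sum(self):
        ds, res = self._fitted()
        bound = res.alphas.sum() + 1e-9
        assert all(abs(res.score_bag(b)) <= bound for b in ds.bags)

    def test_identical_instances_equal_singleton(self):
        ds, res = self._fitted()
        inst = ds.bags[0].instances[0]
        single = Bag("s", 1, [inst])
        triple = Bag("t", 1, [inst, inst, inst])
        assert res.score_bag(triple) == pytest.approx(res.score_bag(single))

    def test_monotone_bag_evidence(self):
        """Appending a positive-sign instance never lowers a round's bag
        vote; a negative-sign instance never raises it."""
        ds, res = self._fitted()
        _, tree = res.ensemble.rounds[0]
        X = ds.feature_matrix()
        conf = tree.predict(X)
        pos = conf[conf > 0]
        neg = conf[conf <= 0]
        if pos.size and neg.size:
            from milboost.boosting import bag_hypothesis
            base_confs = list(conf[:4])
            h0 = bag_hypothesis(base_confs)
            assert bag_hypothesis(base_confs + [pos[0]]) >= h0 - 1e-12
            assert bag_hypothesis(base_confs + [neg[0]]) <= h0 + 1e-12

    def test_empty_model_rejected(self):
        from milboost.boosting import EnsembleModel
        empty = EnsembleModel([], mode="mil", d=3)
        with pytest.raises(ValueError):
            empty.score_instances(np.zeros((1, 3)))

    def test_model_json_roundtrip(self, tmp_path):
        ds, res = self._fitted()
        path = tmp_path / "model.json"
        res.save(path)
        from milboost.boosting import EnsembleModel
        back = EnsembleModel.load(path)
        X = ds.feature_matrix()
        np.testing.assert_array_equal(
            back.score_instances(X), res.score_instances(X)
        )
        assert back.mode == res.ensemble.mode
        assert back.history == [tuple(h) for h in res.ensemble.history]


class TestSummary:
    def test_summary_mentions_key_facts(self, tiny_dataset):
        res = mb.fit(tiny_dataset, T=2)
        text = res.summary()
        assert "mil" in text
        assert "rounds fitted" in text
        assert "epsilon" in text
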