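"""Loss, training loop, and the evaluation statistics."""

import numpy as np
import pytest

from dtdsmil.dsmil_head import MILOutput
from dtdsmil.errors import DataError, DegenerateWarning
from dtdsmil.synthdata import SyntheticBagSpec, gen_feature_bags
from dtdsmil.train_eval import (TrainConfig, choose_threshold,
                                confusion_metrics, delong_ci, evaluate_scores,
                                loss, roc_auc, train)


def mil_out(c_max, c_slide, n=3):
    scores = np.full(n, c_max * 0.5)
    scores[0] = c_max
    return MILOutput(instance_scores=scores, critical_index=0,
                     attention=np.full(n, 1.0 / n), f_slide=np.zeros(2),
                     c_max=c_max, c_slide=c_slide,
                     c=0.5 * (c_max + c_slide))


class TestLoss:
    def test_perfect_prediction_loss_vanishes(self):
        assert loss(mil_out(1.0 - 1e-12, 1.0 - 1e-12), 1) < 1e-9
        assert loss(mil_out(1e-12, 1e-12), 0) < 1e-9

    def test_coin_flip_is_ln2(self):
        assert loss(mil_out(0.5, 0.5), 1) == pytest.approx(np.log(2))
        assert loss(mil_out(0.5, 0.5), 0) == pytest.approx(np.log(2))

    @pytest.mark.parametrize("p", [0.1, 0.37, 0.5, 0.93])
    def test_dual_equals_fused_when_streams_agree(self, p):
        out = mil_out(p, p)
        assert loss(out, 1, "dual_bce") == pytest.approx(loss(out, 1, "fused_bce"))


class TestTrain:
    @pytest.fixture(scope="class")
    def tiny_dataset(self):
        spec = SyntheticBagSpec(n_bags=12, instances_per_bag=9, d=8,
                                grid_shape=(3, 3), mean_shift=4.0, seed=5)
        bags, labels, _ = gen_feature_bags(spec)
        return bags, labels

    def model_cfgs(self):
        return dict(d_enc=8, n_layers=1, n_heads=2, n_points=2, d_ffn=16,
                    dropout=0.0, d_q=8, d_v=8)

    def test_loss_decreases_on_separable_data(self, tiny_dataset):
        bags, labels = tiny_dataset
        _, history = train(bags, labels, self.model_cfgs(),
                           TrainConfig(epochs=8, learning_rate=1e-3, seed=0))
        assert np.mean(history[-2:]) < np.mean(history[:2])

    def test_same_seed_reproduces_parameters(self, tiny_dataset):
        bags, labels = tiny_dataset
        cfg = TrainConfig(epochs=2, learning_rate=1e-3, seed=3)
        m1, _ = train(bags, labels, self.model_cfgs(), cfg)
        m2, _ = train(bags, labels, self.model_cfgs(), cfg)
        for p1, p2 in zip(m1.encoder_.params() + m1.head_.params(),
                          m2.encoder_.params() + m2.head_.params()):
            np.testing.assert_array_equal(p1.data, p2.data)

    def test_zero_learning_rate_leaves_parameters_at_init(self, tiny_dataset):
        bags, labels = tiny_dataset
        m, _ = train(bags, labels, self.model_cfgs(),
                     TrainConfig(epochs=2, learning_rate=0.0, seed=3))
        from dtdsmil.encoder import DeformableTransformerEncoder
        fresh = DeformableTransformerEncoder(
            bags[0].d, m.encoder_.cfg)
        for p1, p2 in zip(m.encoder_.params(), fresh.params()):
            np.testing.assert_array_equal(p1.data, p2.data)

    def test_single_class_dataset_rejected(self, tiny_dataset):
        bags, _ = tiny_dataset
        with pytest.raises(DataError):
            train(bags, np.ones(len(bags), dtype=int), self.model_cfgs(),
                  TrainConfig(epochs=1))


class TestRocAuc:
    def test_printed_example(self):
        assert roc_auc([0.8, 0.35, 0.4, 0.1], [1, 1, 0, 0]) == 0.75

    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_matches_pairwise_brute_force(self, rng):
        for _ in range(20):
            scores = rng.random(15)
            labels = rng.integers(0, 2, 15)
            if labels.min() == labels.max():
                continue
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            brute = np.mean([(1.0 if p > q else 0.5 if p == q else 0.0)
                             for p in pos for q in neg])
            assert roc_auc(scores, labels) == pytest.approx(brute)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.random(30)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        assert roc_auc(np.exp(3 * scores), labels) == pytest.approx(
            roc_auc(scores, labels))

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score
        scores = rng.random(40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        assert roc_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores))


class TestDeLong:
    def test_perfect_separation_collapses_to_point(self):
        lo, hi = delong_ci([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert (lo, hi) == (1.0, 1.0)

    def test_interval_contains_point_auc(self, rng):
        scores = rng.normal(size=30) + np.repeat([0, 1], 15) * 0.8
        labels = np.repeat([0, 1], 15)
        lo, hi = delong_ci(scores, labels)
        assert lo <= roc_auc(scores, labels) <= hi

    def test_coverage_near_nominal_small_sim(self):
        # quick sanity (the full binormal coverage check runs in the
        # acceptance suite)
        rng = np.random.default_rng(99)
        auc0 = 0.8
        mu = np.sqrt(2) * 1.19  # binormal separation giving AUC about 0.8
        from scipy.stats import norm
        mu = np.sqrt(2) * norm.ppf(auc0)
        hits = 0
        reps = 300
        for _ in range(reps):
            x = rng.normal(mu, 1, 60)
            y = rng.normal(0, 1, 60)
            lo, hi = delong_ci(np.concatenate([x, y]),
                               np.repeat([1, 0], 60))
            hits += lo <= auc0 <= hi
        assert 0.90 <= hits / reps <= 0.99


class TestChooseThreshold:
    def test_perfect_separation_returns_midpoint(self):
        t = choose_threshold([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert t == pytest.approx(0.5)

    def test_all_identical_scores_flagged_degenerate(self):
        with pytest.warns(DegenerateWarning):
            t = choose_threshold([0.4] * 4, [0, 1, 0, 1])
        assert t == 0.4

    def test_matches_brute_force_grid(self, rng):
        for _ in range(10):
            scores = np.round(rng.random(20), 3)
            labels = rng.integers(0, 2, 20)
            labels[:2] = [0, 1]
            t = choose_threshold(scores, labels)
            pos, neg = labels == 1, labels == 0

            def j(th):
                pred = scores > th
                return pred[pos].mean() - pred[neg].mean()

            grid = np.linspace(scores.min() - 0.1, scores.max() + 0.1, 2000)
            assert j(t) == pytest.approx(max(j(th) for th in grid), abs=1e-12)


class TestConfusionMetrics:
    def test_arithmetic_example(self):
        # TP=2 FP=1 FN=1 TN=6
        scores = [0.9, 0.8, 0.7, 0.2, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1]
        labels = [1, 1, 0, 1, 0, 0, 0, 0, 0, 0]
        m = confusion_metrics(scores, labels, 0.5)
        assert (m["tp"], m["fp"], m["fn"], m["tn"]) == (2, 1, 1, 6)
        assert m["precision"] == pytest.approx(2 / 3)
        assert m["recall"] == pytest.approx(2 / 3)
        assert m["f1"] == pytest.approx(2 / 3)
        assert m["accuracy"] == pytest.approx(0.8)

    def test_threshold_one_gives_zero_recall(self):
        with pytest.warns(DegenerateWarning):
            m = confusion_metrics([0.3, 0.9], [1, 1], 1.0)
        assert m["recall"] == 0.0 and m["precision"] == 0.0

    def test_threshold_zero_gives_full_recall(self):
        m = confusion_metrics([0.3, 0.9], [1, 1], 0.0)
        assert m["recall"] == 1.0

    def test_strictly_greater_rule(self):
        m = confusion_metrics([0.5], [1], 0.5)
        assert m["tp"] == 0  # score equal to threshold is negative

    def test_threshold_sweep_traces_monotone_roc(self, rng):
        scores = rng.random(40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        tprs, fprs = [], []
        for t in np.sort(np.unique(scores))[::-1]:
            m = confusion_metrics(scores, labels, t)
            tprs.append(m["recall"])
            fprs.append(m["fp"] / max(m["fp"] + m["tn"], 1))
        assert all(a <= b + 1e-12 for a, b in zip(tprs, tprs[1:]))
        assert all(a <= b + 1e-12 for a, b in zip(fprs, fprs[1:]))


def test_evaluate_scores_report_consistency(rng):
    scores = rng.random(30)
    labels = rng.integers(0, 2, 30)
    labels[:2] = [0, 1]
    rep = evaluate_scores(scores, labels, 0.5)
    assert rep.auc_ci_low <= rep.auc <= rep.auc_ci_high
    assert rep.n_pos + rep.n_neg == 30
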