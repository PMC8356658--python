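"""Training recipe and the binary-classification metric suite."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu
from sklearn.metrics import roc_auc_score

from seedsortnet import (
    ConfusionCounts,
    NetworkConfig,
    SyntheticSpec,
    TrainConfig,
    build_network,
    confusion,
    evaluate,
    generate_dataset,
    lr_at_epoch,
    metrics_from_counts,
    predict,
    roc_auc,
    train,
)

RNG = np.random.default_rng(21)


class TestSchedule:
    def test_step_decay_after_thirty_epochs(self):
        cfg = TrainConfig()
        assert lr_at_epoch(cfg, 1) == pytest.approx(0.001)
        assert lr_at_epoch(cfg, 30) == pytest.approx(0.001)
        assert lr_at_epoch(cfg, 31) == pytest.approx(0.0001)
        assert lr_at_epoch(cfg, 60) == pytest.approx(0.0001)
        assert lr_at_epoch(cfg, 61) == pytest.approx(0.00001)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)
        with pytest.raises(ValueError):
            lr_at_epoch(TrainConfig(), 0)


class TestConfusion:
    def test_perfect_predictions(self):
        c = confusion([1] * 10 + [0] * 10, [1] * 10 + [0] * 10)
        assert (c.tp, c.tn, c.fp, c.fn) == (10, 10, 0, 0)

    def test_enumerated_mixed_case(self):
        c = confusion([1, 1, 0, 0], [1, 0, 0, 1])
        assert (c.tp, c.fp, c.tn, c.fn) == (1, 1, 1, 1)

    def test_counts_sum_to_n(self, rng):
        pred = rng.integers(0, 2, size=57)
        true = rng.integers(0, 2, size=57)
        assert confusion(pred, true).total == 57

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            confusion([0, 1], [0, 1, 1])
        with pytest.raises(ValueError):
            confusion([0, 2], [0, 1])
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 1)


class TestMetrics:
    def test_hand_computed_example(self):
        rep = metrics_from_counts(ConfusionCounts(tp=9, tn=9, fp=1, fn=1))
        assert rep.accuracy == pytest.approx(0.9)
        assert rep.precision == pytest.approx(0.9)
        assert rep.recall == pytest.approx(0.9)
        assert rep.f1 == pytest.approx(0.9)

    def test_all_true_positives(self):
        rep = metrics_from_counts(ConfusionCounts(tp=7, tn=0, fp=0, fn=0))
        assert (rep.accuracy, rep.precision, rep.recall, rep.f1) == (1, 1, 1, 1)

    def test_zero_denominator_flagged_not_zeroed(self):
        rep = metrics_from_counts(ConfusionCounts(tp=0, tn=3, fp=0, fn=2))
        assert np.isnan(rep.precision)
        assert "precision" in rep.undefined
        assert rep.recall == 0.0  # defined: tp/(tp+fn) = 0/2

    def test_f1_is_harmonic_mean(self, rng):
        for _ in range(20):
            tp, tn, fp, fn = rng.integers(1, 50, size=4)
            rep = metrics_from_counts(ConfusionCounts(int(tp), int(tn),
                                                      int(fp), int(fn)))
            p, r = rep.precision, rep.recall
            assert rep.f1 == pytest.approx(2 * p * r / (p + r))
            assert rep.accuracy == pytest.approx((tp + tn) / (tp + tn + fp + fn))

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            metrics_from_counts(ConfusionCounts(0, 0, 0, 0))


class TestRocAuc:
    def test_perfect_separation(self):
        rep = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert rep.auc == pytest.approx(1.0)

    def test_constant_scores_give_half(self):
        rep = roc_auc([0.5] * 8, [1, 0, 1, 0, 1, 0, 1, 0])
        assert rep.auc == pytest.approx(0.5)

    def test_enumerated_four_point_curve(self):
        rep = roc_auc([0.9, 0.8, 0.3, 0.2], [1, 0, 1, 0])
        assert rep.auc == pytest.approx(0.75)

    def test_curve_endpoints(self, rng):
        scores = rng.random(30)
        labels = rng.integers(0, 2, size=30)
        labels[0], labels[1] = 0, 1
        rep = roc_auc(scores, labels)
        assert rep.roc[0] == (0.0, 0.0)
        assert rep.roc[-1] == (1.0, 1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])

    def test_matches_mann_whitney_and_sklearn(self, rng):
        """AUC equals U/(n+ * n-) and the library implementation, with ties."""
        for trial in range(5):
            scores = np.round(rng.random(40), 1)  # induce ties
            labels = rng.integers(0, 2, size=40)
            labels[:2] = [0, 1]
            rep = roc_auc(scores, labels)
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            u = mannwhitneyu(pos, neg, alternative="two-sided").statistic
            assert rep.auc == pytest.approx(u / (len(pos) * len(neg)))
            assert rep.auc == pytest.approx(roc_auc_score(labels, scores))


@pytest.fixture(scope="module")
def tiny_run():
    from tests.conftest import TINY_PLAN
    data = generate_dataset(SyntheticSpec(n_per_class=16, image_size=32,
                                          noise_sd=0.0, rng_seed=4))
    cfg = NetworkConfig(input_size=32, stage_plan=TINY_PLAN,
                        root_branch_channels=16)
    net = build_network(cfg, seed=4)
    result = train(net, data, TrainConfig(epochs=10, batch_size=8, rng_seed=4))
    return data, cfg, result


class TestTraining:
    def test_seeded_training_is_reproducible(self, tiny_run):
        data, cfg, result = tiny_run
        net2 = build_network(cfg, seed=4)
        result2 = train(net2, data, TrainConfig(epochs=10, batch_size=8, rng_seed=4))
        losses1 = [h["train_loss"] for h in result.history]
        losses2 = [h["train_loss"] for h in result2.history]
        assert losses1 == losses2

    def test_loss_decreases_on_clean_data(self, tiny_run):
        _, _, result = tiny_run
        losses = [h["train_loss"] for h in result.history]
        assert np.median(losses[-5:]) < np.median(losses[:5])

    def test_history_records_schedule(self, tiny_run):
        _, _, result = tiny_run
        assert [h["lr"] for h in result.history] == [0.001] * len(result.history)
        assert [h["epoch"] for h in result.history] == list(range(1, 11))

    def test_history_csv_written(self, tiny_run, tmp_path):
        _, _, result = tiny_run
        result.history_csv(tmp_path / "history.csv")
        lines = (tmp_path / "history.csv").read_text().strip().splitlines()
        assert lines[0].startswith("epoch,lr,train_loss")
        assert len(lines) == 1 + len(result.history)

    def test_evaluate_produces_full_report(self, tiny_run):
        data, _, result = tiny_run
        counts, report = evaluate(result.network, data, result.normalization)
        assert counts.total == len(data)
        assert 0.0 <= report.auc <= 1.0
        probs = predict(result.network, data, result.normalization)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, rtol=1e-5)

    def test_empty_split_rejected(self, tiny_config):
        import numpy as np
        from seedsortnet import LabeledImageSet
        net = build_network(tiny_config, seed=0)
        empty = LabeledImageSet(np.zeros((0, 32, 32, 3), dtype=np.float32),
                                np.zeros(0, dtype=np.int64))
        with pytest.raises(ValueError):
            train(net, empty, TrainConfig(epochs=1))
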