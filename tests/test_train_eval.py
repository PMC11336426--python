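"""Training protocol, metrics, aggregation, donor protocols."""

import warnings

import numpy as np
import pytest

from rbcsmear.nn import CnnSpec, build_model
from rbcsmear.reference import HELD_OUT_DONOR_METRICS
from rbcsmear.train_eval import (
    TrainConfig,
    aggregate_metrics,
    classification_report,
    cross_validate,
    leave_one_donor_out,
    percentage_deviation,
    regression_report,
    train,
)
from rbcsmear.tiling import Tile, build_dataset

TINY = CnnSpec(input_size=32, channel_scale=1 / 16, fc_widths=(16, 8))


def intensity_separable(n_per_class, levels, size=32, seed=0):
    """Classes distinguished by disjoint intensity ranges; trivially learnable."""
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for label, level in enumerate(levels):
        x = rng.normal(level, 0.05, size=(n_per_class, 1, size, size))
        xs.append(x.astype(np.float32))
        ys.append(np.full(n_per_class, label, dtype=np.int64))
    return np.concatenate(xs), np.concatenate(ys)


def quiet_cfg(**kw):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return TrainConfig(**kw)


class TestTrain:
    def test_separable_classes_learned_within_ten_epochs(self):
        x, y = intensity_separable(200, (-1.0, 1.0))
        model = build_model(TINY, "storage-3", seed=1)
        history = train(model, x, y, quiet_cfg(epochs=10, seed=2, learning_rate=0.01))
        assert max(history["train_accuracy"]) >= 0.95

    def test_zero_learning_rate_plateau_stops_at_epoch_four(self):
        x, y = intensity_separable(20, (-1.0, 1.0))
        spec = CnnSpec(input_size=32, channel_scale=1 / 16, fc_widths=(16, 8), dropout=0.0)
        model = build_model(spec, "storage-3", seed=0)
        cfg = quiet_cfg(epochs=20, learning_rate=0.0, batch_size=64, augment=False, seed=0)
        history = train(model, x, y, cfg)
        losses = history["train_loss"]
        assert len(losses) == 4  # 3 consecutive stalled epochs after the first
        assert losses[0] == pytest.approx(losses[-1])

    def test_same_seed_reproduces_history_exactly(self):
        x, y = intensity_separable(40, (-0.5, 0.5))
        histories = []
        for _ in range(2):
            model = build_model(TINY, "storage-3", seed=5)
            histories.append(
                train(model, x, y, quiet_cfg(epochs=3, seed=6, learning_rate=0.005))
            )
        assert histories[0] == histories[1]

    def test_regression_targets_destandardized(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(60, 1, 32, 32)).astype(np.float32)
        y = rng.uniform(2.3, 3.6, 60).astype(np.float32)
        model = build_model(TINY, "regression", seed=0)
        train(model, x, y, quiet_cfg(epochs=2, seed=1))
        pred = model.predict(x)
        assert 1.0 < pred.mean() < 5.0  # back on the RS scale, not z-scores


class TestCrossValidate:
    def make_dataset(self):
        rng = np.random.default_rng(0)
        pools = {}
        for label, level in ((0, 0.2), (1, 0.8)):
            pools[label] = [
                Tile(pixels=rng.normal(level, 0.03, (32, 32)).astype(np.float32),
                     scan_id=f"{label}", row=i, col=0)
                for i in range(80)
            ]
        return build_dataset(pools, seed=3, train_quota=60, test_quota=10,
                             validation_quota=25, n_folds=5)

    def test_separable_data_every_fold_accurate(self):
        ds = self.make_dataset()
        result = cross_validate(TINY, "storage-3", ds, quiet_cfg(epochs=4, seed=1,
                                                                 learning_rate=0.01))
        assert len(result["folds"]) == 5
        for fold in result["folds"]:
            assert fold["val_accuracy"] >= 0.95
        assert result["mean_val_accuracy"] >= 0.95

    def test_folds_partition_validation_pool(self):
        ds = self.make_dataset()
        val = ds.manifest[ds.manifest.fold >= 0]
        assert len(val) == 2 * 25
        sizes = val.groupby(["class_label", "fold"]).size()
        assert (sizes == 5).all()


class TestClassificationMetrics:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 2, 1, 0])
        rep = classification_report(y, y, n_classes=3)
        assert rep.accuracy == 1.0
        assert rep.f1 == pytest.approx(1.0)
        np.testing.assert_allclose(np.diag(rep.confusion), 1.0)

    def test_hand_tallied_confusion(self):
        """Confusion counts [[8,1,1],[2,6,2],[0,0,10]] give accuracy 24/30."""
        y_true, y_pred = [], []
        counts = [[8, 1, 1], [2, 6, 2], [0, 0, 10]]
        for i, row in enumerate(counts):
            for j, n in enumerate(row):
                y_true += [i] * n
                y_pred += [j] * n
        rep = classification_report(np.array(y_true), np.array(y_pred), n_classes=3)
        assert rep.accuracy == pytest.approx(0.8)
        assert rep.confusion_counts == counts
        np.testing.assert_allclose(rep.confusion[0], [0.8, 0.1, 0.1])

    def test_identities_against_brute_force_tally(self):
        """Accuracy and macro-F1 recomputed by hand loops on 10,000 pairs."""
        rng = np.random.default_rng(99)
        y_true = rng.integers(0, 4, 10_000)
        y_pred = rng.integers(0, 4, 10_000)
        rep = classification_report(y_true, y_pred, n_classes=4)

        hits = sum(1 for t, p in zip(y_true, y_pred) if t == p)
        assert rep.accuracy == pytest.approx(hits / 10_000)

        f1s = []
        for c in range(4):
            tp = sum(1 for t, p in zip(y_true, y_pred) if t == c and p == c)
            fp = sum(1 for t, p in zip(y_true, y_pred) if t != c and p == c)
            fn = sum(1 for t, p in zip(y_true, y_pred) if t == c and p != c)
            prec = tp / (tp + fp)
            rec = tp / (tp + fn)
            f1s.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
        assert rep.f1 == pytest.approx(float(np.mean(f1s)))
        total = np.sum(rep.confusion_counts)
        assert rep.accuracy == pytest.approx(np.trace(rep.confusion_counts) / total)

    def test_single_class_test_set_reports_nan_with_warning(self):
        y_true = np.zeros(10, dtype=int)
        y_pred = np.zeros(10, dtype=int)
        with pytest.warns(UserWarning, match="undefined"):
            rep = classification_report(y_true, y_pred, n_classes=3)
        assert rep.per_class_recall[0] == 1.0
        assert np.isnan(rep.per_class_recall[1])


class TestRegressionMetrics:
    def test_perfect_predictions(self):
        y = np.array([1.0, 2.0, 3.0])
        rep = regression_report(y, y)
        assert rep.mae == 0.0 and rep.rmse == 0.0
        assert rep.pearson_r == pytest.approx(1.0)

    def test_hand_arithmetic_toy_pairs(self):
        rep = regression_report([1, 2, 3], [1.1, 1.9, 3.2])
        assert rep.mae == pytest.approx(0.4 / 3)
        assert rep.rmse >= rep.mae

    def test_constant_prediction_pearson_nan(self):
        with pytest.warns(UserWarning, match="Pearson"):
            rep = regression_report([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])
        assert np.isnan(rep.pearson_r)
        assert rep.mae == pytest.approx(2 / 3)

    def test_rmse_at_least_mae_random(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            t = rng.normal(size=50)
            p = t + rng.normal(size=50)
            rep = regression_report(t, p)
            assert rep.rmse >= rep.mae - 1e-12

    def test_both_r_squared_conventions_reported(self):
        rng = np.random.default_rng(1)
        t = rng.normal(size=200)
        p = 0.8 * t + rng.normal(0, 0.5, 200)
        rep = regression_report(t, p)
        assert rep.r2 is not None and rep.r2_pearson is not None
        assert rep.r2 <= 1.0
        assert rep.r2_pearson == pytest.approx(rep.pearson_r**2)


class TestPercentageDeviation:
    @pytest.mark.parametrize(
        "error, expected", [(0.164, 13.0), (0.212, 16.8), (0.17, 13.5), (0.0, 0.0)]
    )
    def test_rs_range_deviations(self, error, expected):
        assert percentage_deviation(error, (2.30, 3.56)) == expected

    def test_bad_range_rejected(self):
        with pytest.raises(ValueError):
            percentage_deviation(0.1, (3.0, 2.0))


class TestAggregation:
    def test_reference_cohort_aggregates(self):
        """Printed per-donor rows reproduce the printed mean and SD."""
        per_donor = {
            d: {"accuracy": m[0], "precision": m[1], "recall": m[2], "f1": m[3]}
            for d, m in HELD_OUT_DONOR_METRICS.items()
        }
        means, sds = aggregate_metrics(per_donor)
        assert round(means["accuracy"], 2) == 0.61
        assert round(sds["accuracy"], 2) == 0.07
        assert round(means["precision"], 3) == 0.624
        assert round(means["recall"], 3) == 0.636
        assert round(means["f1"], 3) == 0.623
        assert round(sds["precision"], 3) == 0.099
        assert round(sds["recall"], 3) == 0.100
        assert round(sds["f1"], 3) == 0.100

    def test_sample_standard_deviation_convention(self):
        per = {"a": {"m": 1.0}, "b": {"m": 2.0}, "c": {"m": 3.0}}
        means, sds = aggregate_metrics(per)
        assert means["m"] == 2.0
        assert sds["m"] == pytest.approx(1.0)  # ddof=1


class TestLeaveOneDonorOut:
    def test_exchangeable_donors_agree(self):
        """Identically distributed donors give statistically similar accuracy."""
        data = {}
        for i, donor in enumerate(("d1", "d2")):
            x, y = intensity_separable(60, (-1.0, 1.0), seed=10 + i)
            data[donor] = (x, y)
        result = leave_one_donor_out(
            data, TINY, "storage-3", quiet_cfg(epochs=4, seed=3, learning_rate=0.01)
        )
        accs = [result["per_donor"][d].accuracy for d in ("d1", "d2")]
        assert all(a >= 0.8 for a in accs)
        assert abs(accs[0] - accs[1]) <= 0.2
        assert set(result["mean"]) == {"accuracy", "precision", "recall", "f1"}

    def test_requires_two_donors(self):
        with pytest.raises(ValueError):
            leave_one_donor_out({"only": (np.zeros((1, 1, 32, 32)), np.zeros(1))},
                                TINY, "storage-3", quiet_cfg())
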