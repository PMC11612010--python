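"""Tests for feature assembly, prediction metrics and the SVM protocol."""

import numpy as np
import pandas as pd
import pytest

import preictal as p
from preictal.errors import (DegenerateInputError, FeatureAssemblyError,
                             StratificationError)
from preictal.features import MODE_COLUMNS
from preictal.prediction import compute_metrics, split_indices


class TestFeatureExtraction:
    def test_fusion_has_23_named_columns(self, small_features):
        features, _ = small_features
        assert list(features.values.columns) == list(MODE_COLUMNS["fusion"])
        assert features.values.shape == (60, 23)
        assert not features.values.isna().any().any()

    def test_mode_column_counts(self, small_features):
        features, _ = small_features
        for mode, n in (("fusion", 23), ("microstate", 12),
                        ("nonlinear", 6), ("spectrum", 5)):
            sub = p.assemble_features(features, mode=mode)
            assert sub.values.shape[1] == n
            assert sub.mode == mode

    def test_missing_column_rejected(self, small_features):
        features, _ = small_features
        df = features.values.drop(columns=["mlzc"])
        with pytest.raises(FeatureAssemblyError, match="mlzc"):
            p.assemble_features(df, labels=features.labels, mode="nonlinear")

    def test_nan_rejected(self, small_features):
        features, _ = small_features
        df = features.values.copy()
        df.loc[0, "tbr"] = np.nan
        with pytest.raises(FeatureAssemblyError, match="tbr"):
            p.assemble_features(df, labels=features.labels, mode="spectrum")

    def test_unknown_mode_rejected(self, small_features):
        features, _ = small_features
        with pytest.raises(FeatureAssemblyError):
            p.assemble_features(features, mode="everything")

    def test_ranges_sane(self, small_features):
        features, _ = small_features
        df = features.values
        cov = df[[f"coverage_{c}" for c in "ABCD"]].to_numpy()
        assert np.all(cov >= 0) and np.all(cov <= 1)
        assert np.allclose(cov.sum(axis=1) + 0.0, 1.0, atol=1e-9) or np.all(
            cov.sum(axis=1) <= 1.0 + 1e-9
        )
        for col in ("lzc_mean", "mlzc", "perm_en", "mperm_en"):
            assert np.all(df[col] >= 0)
        assert np.all(df["tbr"] > 0)


class TestComputeMetrics:
    def test_sensitivity_28_of_30(self):
        truth = np.array([1] * 30 + [0] * 30)
        pred = truth.copy()
        pred[:2] = 0  # 2 false negatives
        scores = pred + np.linspace(0, 0.1, 60)
        m = compute_metrics(pred, truth, scores, interictal_hours=1.0)
        assert m["sensitivity_pct"] == pytest.approx(100 * 28 / 30)
        assert m["specificity_pct"] == pytest.approx(100.0)

    def test_perfect_prediction(self):
        truth = np.array([0, 1] * 20)
        scores = truth.astype(float)
        m = compute_metrics(truth, truth, scores, interictal_hours=2.0)
        assert m["accuracy_pct"] == 100.0
        assert m["kappa_pct"] == pytest.approx(100.0)
        assert m["fpr_per_hour"] == 0.0
        assert m["auc"] == 1.0

    def test_fpr_per_hour(self):
        truth = np.array([0] * 10 + [1] * 10)
        pred = truth.copy()
        pred[:2] = 1  # 2 false positives
        m = compute_metrics(pred, truth, pred.astype(float), interictal_hours=2.0)
        assert m["fpr_per_hour"] == pytest.approx(1.0)

    def test_event_merged_fpr(self):
        truth = np.zeros(8, dtype=int)
        truth[6:] = 1
        pred = np.array([1, 1, 0, 1, 0, 0, 1, 1])  # FPs at 0,1 (one event) and 3
        m = compute_metrics(pred, truth, pred.astype(float), 1.0,
                            event_merged_fpr=True,
                            epoch_indices=np.arange(8))
        assert m["fpr_per_hour"] == pytest.approx(2.0)

    def test_label_swap_swaps_sens_spec(self):
        rng = np.random.default_rng(0)
        truth = rng.integers(0, 2, 100)
        pred = np.where(rng.random(100) < 0.8, truth, 1 - truth)
        scores = pred.astype(float)
        m1 = compute_metrics(pred, truth, scores, 1.0)
        m2 = compute_metrics(1 - pred, 1 - truth, -scores, 1.0)
        assert m1["sensitivity_pct"] == pytest.approx(m2["specificity_pct"])
        assert m1["specificity_pct"] == pytest.approx(m2["sensitivity_pct"])

    def test_single_class_truth_rejected(self):
        with pytest.raises(DegenerateInputError):
            compute_metrics(np.ones(5), np.ones(5), np.ones(5), 1.0)


class TestSplitIndices:
    def test_600_epochs_give_60_test(self):
        labels = ["interictal"] * 300 + ["preictal"] * 300
        proto = p.PredictionProtocol(seed=3)
        train, test = split_indices(labels, proto, 0)
        assert len(test) == 60
        assert len(train) == 540
        assert len(set(train) & set(test)) == 0
        arr = np.asarray(labels)
        assert (arr[test] == "preictal").sum() == 30

    def test_deterministic_per_repetition(self):
        labels = ["interictal"] * 50 + ["preictal"] * 50
        proto = p.PredictionProtocol(seed=5)
        t1 = split_indices(labels, proto, 2)
        t2 = split_indices(labels, proto, 2)
        t3 = split_indices(labels, proto, 3)
        assert np.array_equal(t1[1], t2[1])
        assert not np.array_equal(t1[1], t3[1])

    def test_single_class_rejected(self):
        with pytest.raises(StratificationError):
            split_indices(["preictal"] * 20, p.PredictionProtocol(), 0)


def _toy_features(n_per_class=40, sep=3.0, seed=0):
    """Small separable fusion-shaped matrix for fast protocol tests."""
    rng = np.random.default_rng(seed)
    cols = list(MODE_COLUMNS["fusion"])
    rows, labels = [], []
    for label, shift in (("interictal", 0.0), ("preictal", sep)):
        block = rng.normal(0, 1, (n_per_class, len(cols)))
        block[:, :4] += shift  # separate along the duration columns
        rows.append(block)
        labels += [label] * n_per_class
    df = pd.DataFrame(np.vstack(rows), columns=cols)
    return p.FeatureMatrix(df, labels)


class TestRunPrediction:
    def test_separable_features_high_accuracy(self):
        proto = p.PredictionProtocol(n_repetitions=3, seed=1,
                                     c_grid=(1.0, 8.0), gamma_grid=(0.01, 0.1))
        report = p.run_prediction(_toy_features(sep=4.0), proto)
        assert report.mean("accuracy_pct") >= 95.0
        assert report.mean("auc") >= 0.98
        assert len(report.repetitions) == 3
        assert {"C", "gamma", "repetition"} <= set(report.repetitions[0])

    def test_permuted_labels_chance_auc(self):
        features = _toy_features(n_per_class=60, sep=4.0, seed=2)
        rng = np.random.default_rng(9)
        permuted = list(rng.permutation(features.labels))
        shuffled = p.FeatureMatrix(features.values, permuted)
        proto = p.PredictionProtocol(n_repetitions=5, seed=2,
                                     c_grid=(1.0,), gamma_grid=(0.05,))
        report = p.run_prediction(shuffled, proto)
        assert 0.3 <= report.mean("auc") <= 0.7

    def test_bitwise_reproducible(self):
        proto = p.PredictionProtocol(n_repetitions=2, seed=4,
                                     c_grid=(1.0, 4.0), gamma_grid=(0.05,))
        r1 = p.run_prediction(_toy_features(seed=3), proto)
        r2 = p.run_prediction(_toy_features(seed=3), proto)
        assert r1.repetitions == r2.repetitions
        assert r1.summary == r2.summary

    def test_leakage_canary(self):
        # plant a column that encodes the label on TEST rows only (at the same
        # scale as the noise features) and is pure noise on training rows; if
        # any fitting step saw the test rows the model could exploit it, so a
        # leak-free protocol must stay at chance on these unseparable features
        features = _toy_features(n_per_class=60, sep=0.0, seed=5)
        y = np.array([1 if lab == "preictal" else 0 for lab in features.labels])
        accs = []
        for run in range(5):
            proto = p.PredictionProtocol(n_repetitions=1, seed=6 + run,
                                         c_grid=(1.0, 32.0),
                                         gamma_grid=(0.05, 0.5))
            canary = features.values.copy()
            _, test = split_indices(features.labels, proto, 0)
            canary.loc[test, "tbr"] = 2.0 * y[test] - 1.0
            poisoned = p.FeatureMatrix(canary, features.labels)
            accs.append(p.run_prediction(poisoned, proto).mean("accuracy_pct"))
        # unseparable base features: accuracy must remain near chance
        assert float(np.mean(accs)) <= 70.0

    def test_report_json_round_trip(self, tmp_path):
        import json

        proto = p.PredictionProtocol(n_repetitions=2, seed=7,
                                     c_grid=(1.0,), gamma_grid=(0.05,))
        report = p.run_prediction(_toy_features(seed=6), proto)
        path = tmp_path / "report.json"
        report.to_json(path)
        payload = json.loads(path.read_text())
        assert payload["summary"]["accuracy_pct"]["mean"] == report.mean(
            "accuracy_pct"
        )
        assert payload["protocol"]["seed"] == 7

    def test_single_class_features_rejected(self):
        features = _toy_features()
        bad = p.FeatureMatrix(features.values, ["interictal"] * len(features.labels))
        with pytest.raises(StratificationError):
            p.run_prediction(bad, p.PredictionProtocol(n_repetitions=1))

    def test_yaml_protocol(self, tmp_path):
        path = tmp_path / "proto.yaml"
        path.write_text("n_repetitions: 4\nseed: 12\nc_grid: [1, 8]\n")
        proto = p.PredictionProtocol.from_yaml(path)
        assert proto.n_repetitions == 4
        assert proto.c_grid == (1.0, 8.0)
        assert proto.gamma_grid == p.PredictionProtocol().gamma_grid


class TestEndToEnd:
    def test_planted_dataset_separates(self, small_features, small_dataset):
        features, templates = small_features
        epochs, _ = small_dataset
        proto = p.PredictionProtocol(n_repetitions=3, seed=0,
                                     c_grid=(1.0, 8.0, 64.0),
                                     gamma_grid=(2**-5, 2**-3, 2**-1))
        report = p.run_prediction(features, proto)
        assert report.mean("accuracy_pct") >= 90.0
        assert report.mean("auc") >= 0.95
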