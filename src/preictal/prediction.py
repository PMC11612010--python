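"""Individual-level SVM prediction protocol and its metrics.

The protocol holds out a stratified 10% test split, tunes an RBF-kernel SVM
by 5-fold cross-validated grid search over C and gamma on the remaining
90%, refits and evaluates on the held-out split, and repeats the whole
procedure ten times with different split seeds.  Feature standardization is
part of the fitted pipeline, so normalization parameters are estimated on
training folds only and the held-out split never leaks into model
selection.

Metrics: accuracy, sensitivity (preictal positive), specificity, Cohen's
kappa (all in percent), ROC AUC, and false alarms per hour of interictal
recording evaluated (epoch-level counting by default; consecutive false
positives can be merged into single alarm events behind a flag).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .errors import DegenerateInputError, StratificationError
from .features import FeatureMatrix
from .simulate import INTERICTAL, PREICTAL


@dataclass
class PredictionProtocol:
    """Configuration of the repeated hold-out evaluation."""

    mode: str = "fusion"
    test_fraction: float = 0.1
    n_repetitions: int = 10
    cv_folds: int = 5
    c_grid: tuple[float, ...] = tuple(float(2.0**e) for e in range(-3, 8))
    gamma_grid: tuple[float, ...] = tuple(float(2.0**e) for e in range(-7, 4))
    seed: int = 0
    epoch_length_s: float = 3.0
    positive_label: str = PREICTAL
    event_merged_fpr: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PredictionProtocol":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("c_grid", "gamma_grid"):
            if key in raw:
                raw[key] = tuple(float(v) for v in raw[key])
        return cls(**raw)


@dataclass
class ClassifierReport:
    """Per-repetition metrics with across-repetition means and SDs."""

    repetitions: list[dict]
    summary: dict[str, dict[str, float]]
    protocol: PredictionProtocol | None = None

    def to_json(self, path=None) -> str:
        payload = {
            "repetitions": self.repetitions,
            "summary": self.summary,
            "protocol": asdict(self.protocol) if self.protocol else None,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def mean(self, metric: str) -> float:
        return self.summary[metric]["mean"]


def _merge_alarm_count(fp_mask: np.ndarray, indices: np.ndarray) -> int:
    """Count runs of consecutive (by original epoch index) false positives."""
    if not fp_mask.any():
        return 0
    order = np.argsort(indices)
    idx = indices[order]
    fp = fp_mask[order]
    count = 0
    prev_idx = None
    for i, is_fp in zip(idx, fp):
        if is_fp and not (prev_idx is not None and i == prev_idx + 1):
            count += 1
        prev_idx = i if is_fp else None
    return count


def compute_metrics(predictions: np.ndarray, truth: np.ndarray,
                    scores: np.ndarray, interictal_hours: float, *,
                    event_merged_fpr: bool = False,
                    epoch_indices: np.ndarray | None = None) -> dict[str, float]:
    """Metric set for one evaluation; labels are 0 (interictal) / 1 (preictal)."""
    from sklearn.metrics import cohen_kappa_score, roc_auc_score

    predictions = np.asarray(predictions, dtype=int)
    truth = np.asarray(truth, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if not (predictions.shape == truth.shape == scores.shape):
        raise ValueError("predictions, truth and scores must align")
    if interictal_hours <= 0:
        raise ValueError("interictal_hours must be positive")
    if len(np.unique(truth)) < 2:
        raise DegenerateInputError("AUC undefined with a single-class truth")

    tp = int(((predictions == 1) & (truth == 1)).sum())
    fn = int(((predictions == 0) & (truth == 1)).sum())
    fp = int(((predictions == 1) & (truth == 0)).sum())
    tn = int(((predictions == 0) & (truth == 0)).sum())
    if event_merged_fpr:
        fp_mask = (predictions == 1) & (truth == 0)
        idx = (epoch_indices if epoch_indices is not None
               else np.arange(len(predictions)))
        false_alarms = _merge_alarm_count(fp_mask, np.asarray(idx))
    else:
        false_alarms = fp
    return {
        "accuracy_pct": 100.0 * (tp + tn) / len(truth),
        "sensitivity_pct": 100.0 * tp / (tp + fn) if tp + fn else float("nan"),
        "specificity_pct": 100.0 * tn / (tn + fp) if tn + fp else float("nan"),
        "fpr_per_hour": false_alarms / interictal_hours,
        "auc": float(roc_auc_score(truth, scores)),
        "kappa_pct": 100.0 * float(cohen_kappa_score(truth, predictions)),
    }


def split_indices(labels: "list[str] | np.ndarray", protocol: PredictionProtocol,
                  repetition: int) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic stratified train/test indices for one repetition."""
    from sklearn.model_selection import train_test_split

    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise StratificationError("need at least 2 epochs in each class")
    idx = np.arange(len(labels))
    train, test = train_test_split(
        idx, test_size=protocol.test_fraction, stratify=labels,
        random_state=protocol.seed + repetition,
    )
    return np.sort(train), np.sort(test)


def run_prediction(features: FeatureMatrix,
                   protocol: PredictionProtocol | None = None) -> ClassifierReport:
    """Run the repeated hold-out SVM protocol on a feature matrix."""
    from sklearn.model_selection import GridSearchCV, StratifiedKFold
    from sklearn.pipeline import Pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    protocol = protocol or PredictionProtocol()
    X = features.values.to_numpy(dtype=float)
    y = np.asarray([1 if lab == protocol.positive_label else 0
                    for lab in features.labels])
    if len(np.unique(y)) < 2:
        raise StratificationError("both classes must be present")

    reps = []
    for rep in range(protocol.n_repetitions):
        train, test = split_indices(features.labels, protocol, rep)
        if len(np.unique(y[test])) < 2 or len(np.unique(y[train])) < 2:
            raise StratificationError(f"repetition {rep}: single-class split")
        pipe = Pipeline([
            ("scale", StandardScaler()),
            ("svm", SVC(kernel="rbf")),
        ])
        grid = GridSearchCV(
            pipe,
            {"svm__C": list(protocol.c_grid), "svm__gamma": list(protocol.gamma_grid)},
            cv=StratifiedKFold(protocol.cv_folds, shuffle=True,
                               random_state=protocol.seed + rep),
            scoring="accuracy",
        )
        grid.fit(X[train], y[train])
        model = grid.best_estimator_
        pred = model.predict(X[test])
        scores = model.decision_function(X[test])
        n_inter_test = int((y[test] == 0).sum())
        interictal_hours = n_inter_test * protocol.epoch_length_s / 3600.0
        metrics = compute_metrics(
            pred, y[test], scores, interictal_hours,
            event_merged_fpr=protocol.event_merged_fpr, epoch_indices=test,
        )
        metrics["repetition"] = rep
        metrics["C"] = float(grid.best_params_["svm__C"])
        metrics["gamma"] = float(grid.best_params_["svm__gamma"])
        reps.append(metrics)

    metric_names = ("accuracy_pct", "sensitivity_pct", "specificity_pct",
                    "fpr_per_hour", "auc", "kappa_pct")
    summary = {
        name: {
            "mean": float(np.mean([r[name] for r in reps])),
            "sd": float(np.std([r[name] for r in reps], ddof=1))
            if len(reps) > 1 else 0.0,
        }
        for name in metric_names
    }
    return ClassifierReport(reps, summary, protocol)
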