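"""Per-epoch feature extraction and assembly of the fused feature matrix.

For every 3-second epoch the pipeline computes 23 named features:

* 12 microstate parameters -- mean duration, time coverage and occurrence
  frequency for each of the four classes A-D, from the smoothed backfitted
  label sequence;
* 6 nonlinear features -- three EEG Lempel-Ziv complexities (mean, median
  and mid-range thresholds, channel-averaged), the microstate LZC, the EEG
  permutation entropy (channel-averaged) and the microstate permutation
  entropy;
* 5 spectral features -- absolute delta/theta/alpha/beta power
  (channel-averaged) and the theta-to-beta ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .complexity import (OrdinalConfig, binarize, lzc, mlzc, mperm_entropy,
                         perm_entropy)
from .errors import FeatureAssemblyError, LengthError
from .microstates import (UNASSIGNED, MicrostateSequence, MicrostateTemplates,
                          backfit, microstate_parameters, smooth_sequence)
from .preprocess import EpochSet
from .spectral import band_powers

CLASS_LETTERS = ("A", "B", "C", "D")

MICROSTATE_COLUMNS = tuple(
    f"{metric}_{letter}"
    for metric in ("duration", "coverage", "occurrence")
    for letter in CLASS_LETTERS
)
NONLINEAR_COLUMNS = ("lzc_mean", "lzc_median", "lzc_mid_p", "mlzc",
                     "perm_en", "mperm_en")
SPECTRAL_COLUMNS = ("delta", "theta", "alpha", "beta", "tbr")

MODE_COLUMNS: dict[str, tuple[str, ...]] = {
    "microstate": MICROSTATE_COLUMNS,
    "nonlinear": NONLINEAR_COLUMNS,
    "spectrum": SPECTRAL_COLUMNS,
    "fusion": MICROSTATE_COLUMNS + NONLINEAR_COLUMNS + SPECTRAL_COLUMNS,
}


@dataclass
class FeatureMatrix:
    """Named feature columns per epoch plus the per-epoch state labels."""

    values: pd.DataFrame
    labels: list[str]
    mode: str = "fusion"

    def __post_init__(self) -> None:
        if len(self.values) != len(self.labels):
            raise ValueError("one label per feature row required")
        if self.values.columns.duplicated().any():
            raise ValueError("feature column names must be unique")


def _dropped_unassigned(seq: MicrostateSequence) -> np.ndarray:
    return seq.labels[seq.labels != UNASSIGNED]


def extract_features(epochs: EpochSet, templates: MicrostateTemplates, *,
                     min_corr: float = 0.5, smooth_ms: float = 32.0,
                     ordinal: OrdinalConfig | None = None,
                     spectral_method: str = "periodogram") -> FeatureMatrix:
    """Compute the full 23-column feature table for a labeled epoch set.

    Microstate sequences are backfitted per epoch with the given templates,
    smoothed, and reduced to temporal parameters; the microstate-based
    complexity features are computed on the sequence with unassigned samples
    dropped.  An epoch whose deduplicated sequence is too short for the
    microstate permutation entropy aborts assembly with an error naming the
    epoch.
    """
    ordinal = ordinal or OrdinalConfig(embedding_dim=4, time_delay=1)
    rows = []
    for idx in range(epochs.n_epochs):
        epoch = epochs.epochs[idx]
        row: dict[str, float] = {}

        seq = backfit(templates, epoch, sample_rate=epochs.sample_rate,
                      min_corr=min_corr)
        seq = smooth_sequence(seq, smooth_ms)
        params = microstate_parameters(seq)
        for ci, letter in enumerate(CLASS_LETTERS[: templates.k]):
            row[f"duration_{letter}"] = params.mean_duration_ms[ci]
            row[f"coverage_{letter}"] = params.coverage_fraction[ci]
            row[f"occurrence_{letter}"] = params.occurrence_per_s[ci]

        assigned = _dropped_unassigned(seq)
        if assigned.size == 0:
            raise FeatureAssemblyError(
                f"epoch {idx}: no samples assigned to any microstate"
            )
        row["mlzc"] = mlzc(assigned).normalized
        try:
            row["mperm_en"] = mperm_entropy(
                assigned, OrdinalConfig(templates.k, ordinal.time_delay)
            )
        except LengthError as exc:
            raise FeatureAssemblyError(f"epoch {idx}: {exc}") from exc

        for kind in ("mean", "median", "mid_p"):
            vals = [lzc(binarize(ch, kind)).normalized for ch in epoch]
            row[f"lzc_{kind}"] = float(np.mean(vals))
        row["perm_en"] = float(np.mean([perm_entropy(ch, ordinal) for ch in epoch]))

        _, avg = band_powers(epoch, epochs.sample_rate, method=spectral_method)
        row["delta"], row["theta"], row["alpha"], row["beta"], row["tbr"] = (
            avg.delta, avg.theta, avg.alpha, avg.beta, avg.tbr,
        )
        rows.append(row)

    df = pd.DataFrame(rows, columns=list(MODE_COLUMNS["fusion"]))
    return FeatureMatrix(df, list(epochs.labels), "fusion")


def assemble_features(features: "FeatureMatrix | pd.DataFrame",
                      labels: list[str] | None = None,
                      mode: str = "fusion") -> FeatureMatrix:
    """Select the feature-family columns for ``mode`` and validate them.

    ``mode`` is one of ``fusion`` (all 23 columns), ``microstate``,
    ``nonlinear`` or ``spectrum``.  Missing columns or missing values abort
    with an error naming what is absent.
    """
    if isinstance(features, FeatureMatrix):
        df, labels = features.values, features.labels
    else:
        df = features
        if labels is None:
            raise FeatureAssemblyError("labels required with a bare DataFrame")
    if mode not in MODE_COLUMNS:
        raise FeatureAssemblyError(
            f"unknown mode {mode!r}; expected one of {sorted(MODE_COLUMNS)}"
        )
    wanted = MODE_COLUMNS[mode]
    missing = [c for c in wanted if c not in df.columns]
    if missing:
        raise FeatureAssemblyError(f"missing feature columns: {', '.join(missing)}")
    sub = df[list(wanted)]
    bad = sub.isna().any(axis=0)
    if bad.any():
        raise FeatureAssemblyError(
            f"missing values in columns: {', '.join(sub.columns[bad])}"
        )
    return FeatureMatrix(sub.copy(), list(labels), mode)
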