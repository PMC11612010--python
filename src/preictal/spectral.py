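"""Absolute band power and the theta-to-beta ratio (TBR).

Powers are computed from a one-sided periodogram of the full epoch
(rectangular window by default, Welch behind a flag), scaled so the bin
powers sum to the mean squared amplitude of the signal.  Band edges are
half-open ``[low, high)`` so every frequency bin is counted exactly once:
delta [1, 4), theta [4, 8), alpha [8, 12), beta [12, 30) Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import DataCompletenessError, DegenerateInputError, LengthError
from .preprocess import EpochSet

BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
}

BAND_NAMES = ("delta", "theta", "alpha", "beta", "tbr")


@dataclass
class BandPowerSet:
    """Absolute power per band in uV^2 plus the theta/beta ratio."""

    delta: float
    theta: float
    alpha: float
    beta: float
    tbr: float

    def as_array(self) -> np.ndarray:
        return np.array([self.delta, self.theta, self.alpha, self.beta, self.tbr])


def periodogram_power(x: np.ndarray, rate: float, *,
                      method: str = "periodogram") -> tuple[np.ndarray, np.ndarray]:
    """One-sided power spectrum whose bins sum to ``mean(x**2)``.

    Returns ``(freqs, power)`` for a 1-D signal.  ``method`` may be
    ``"periodogram"`` (rectangular window over the full epoch, the default)
    or ``"welch"``.
    """
    x = np.asarray(x, dtype=float)
    if method == "periodogram":
        freqs, psd = sps.periodogram(x, fs=rate, window="boxcar", scaling="density")
    elif method == "welch":
        freqs, psd = sps.welch(x, fs=rate, nperseg=min(x.size, int(rate)),
                               scaling="density")
    else:
        raise ValueError(f"unknown spectral method {method!r}")
    df = freqs[1] - freqs[0] if freqs.size > 1 else 1.0
    return freqs, psd * df  # density * bin width -> bin power, sums to mean square


def band_powers(epoch: np.ndarray, rate: float, *,
                method: str = "periodogram",
                bands: dict[str, tuple[float, float]] | None = None,
                ) -> tuple[list[BandPowerSet], BandPowerSet]:
    """Per-channel band powers of a ``channels x samples`` epoch, plus the
    channel average.

    Raises if beta power is exactly zero in the channel average (TBR
    undefined).  Per-channel TBR is NaN where beta is zero.
    """
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    if epoch.shape[1] < rate:
        raise LengthError("need at least 1 s of samples for band powers")
    bands = bands or BANDS
    per_channel: list[BandPowerSet] = []
    sums = np.zeros(4)
    for ch in epoch:
        freqs, power = periodogram_power(ch, rate, method=method)
        vals = {}
        for name, (lo, hi) in bands.items():
            sel = (freqs >= lo) & (freqs < hi)
            vals[name] = float(power[sel].sum())
        tbr = vals["theta"] / vals["beta"] if vals["beta"] > 0 else float("nan")
        per_channel.append(BandPowerSet(vals["delta"], vals["theta"],
                                        vals["alpha"], vals["beta"], tbr))
        sums += np.array([vals["delta"], vals["theta"], vals["alpha"], vals["beta"]])
    avg = sums / epoch.shape[0]
    if avg[3] == 0:
        raise DegenerateInputError("beta power is zero; TBR undefined")
    average = BandPowerSet(avg[0], avg[1], avg[2], avg[3], avg[1] / avg[3])
    return per_channel, average


@dataclass
class PowerTable:
    """Group x subject x (band | channel) power array with axis labels."""

    values: np.ndarray
    groups: list[str]
    subjects: list[str]
    columns: list[str]
    level: str = "band"  # "band" | "channel"

    def to_frame(self):
        import pandas as pd

        frames = []
        for gi, g in enumerate(self.groups):
            df = pd.DataFrame(self.values[gi], index=self.subjects,
                              columns=self.columns)
            df.insert(0, "group", g)
            frames.append(df.reset_index(names="subject"))
        return pd.concat(frames, ignore_index=True)


def power_tables(epoch_sets: "dict[str, EpochSet]",
                 groups: tuple[str, str] = ("interictal", "preictal"), *,
                 channel_band: str = "delta",
                 method: str = "periodogram") -> tuple[PowerTable, PowerTable]:
    """Band-level and channel-level group power tables.

    ``epoch_sets`` maps subject id to that subject's labeled epochs; both
    group labels must be present for every subject.  The band-level table
    (group x subject x 5) averages over channels and epochs; the
    channel-level table (group x subject x n_channels) holds the power of
    ``channel_band`` per channel.
    """
    subjects = sorted(epoch_sets)
    first = epoch_sets[subjects[0]]
    n_ch = first.epochs.shape[1]
    band_tab = np.zeros((2, len(subjects), 5))
    chan_tab = np.zeros((2, len(subjects), n_ch))
    band_idx = list(BANDS).index(channel_band)
    for si, subj in enumerate(subjects):
        es = epoch_sets[subj]
        for gi, group in enumerate(groups):
            eps = es.select(group)
            if eps.shape[0] == 0:
                raise DataCompletenessError(
                    f"subject {subj!r} has no {group!r} epochs"
                )
            avg_sets = []
            chan_vals = np.zeros((eps.shape[0], n_ch))
            for ei, ep in enumerate(eps):
                per_ch, avg = band_powers(ep, es.sample_rate, method=method)
                avg_sets.append(avg.as_array())
                chan_vals[ei] = [p.as_array()[band_idx] for p in per_ch]
            band_tab[gi, si] = np.mean(avg_sets, axis=0)
            chan_tab[gi, si] = chan_vals.mean(axis=0)
    cols_band = list(BAND_NAMES)
    cols_chan = first.channel_labels or [f"ch{i}" for i in range(n_ch)]
    return (
        PowerTable(band_tab, list(groups), subjects, cols_band, "band"),
        PowerTable(chan_tab, list(groups), subjects, list(cols_chan), "channel"),
    )
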