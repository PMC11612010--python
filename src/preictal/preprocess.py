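"""Preprocessing chain and epoch segmentation for scalp EEG.

The chain reduces a raw clinical recording to the analysis-ready form used by
every downstream module: the 19 standard 10-20 channels, 250 Hz, 1-40 Hz
band-pass with a 48-52 Hz power-line band-stop, common average reference, and
spherical-spline replacement of channels whose amplitude exceeds a threshold
on too large a fraction of samples.  Filters are windowed-sinc FIR applied
zero-phase (forward-backward), with a 1 Hz transition band.

Amplitude-threshold interpolation stands in for automatic ICA artifact
rejection; an ``artifact_hook`` callable can be supplied to plug in an
external ICA (or any other) cleaning step between filtering and referencing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from numpy.polynomial import legendre
from scipy import signal

from .errors import LengthError, MontageError, UnrecoverableDataError
from .io import EEGRecording, STANDARD_19

logger = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    target_rate: output sampling rate in Hz.
    band_pass: (low, high) pass band edges in Hz.
    band_stop: (low, high) stop band edges in Hz (power-line notch).
    amplitude_threshold_uv: peak amplitude above which a sample counts as bad.
    bad_fraction: fraction of bad samples above which a channel is replaced.
    transition_bandwidth_hz: FIR transition band width.
    channels: montage to retain (defaults to the 19-channel 10-20 set).
    artifact_hook: optional callable ``f(recording) -> recording`` run after
        filtering, before referencing/interpolation (e.g. an external ICA).
    """

    target_rate: float = 250.0
    band_pass: tuple[float, float] = (1.0, 40.0)
    band_stop: tuple[float, float] = (48.0, 52.0)
    amplitude_threshold_uv: float = 150.0
    bad_fraction: float = 0.2
    transition_bandwidth_hz: float = 1.0
    channels: tuple[str, ...] = STANDARD_19
    artifact_hook: Callable[[EEGRecording], EEGRecording] | None = None

    @classmethod
    def from_yaml(cls, path) -> "PreprocessConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in (
            "target_rate",
            "amplitude_threshold_uv",
            "bad_fraction",
            "transition_bandwidth_hz",
        ):
            if key in raw:
                kwargs[key] = float(raw[key])
        for key in ("band_pass", "band_stop"):
            if key in raw:
                kwargs[key] = tuple(float(v) for v in raw[key])
        if "channels" in raw:
            kwargs["channels"] = tuple(raw["channels"])
        return cls(**kwargs)


@dataclass
class EpochSet:
    """Fixed-length labeled epochs: ``epochs`` is n_epochs x channels x samples."""

    epochs: np.ndarray
    labels: list[str]
    epoch_length_s: float
    sample_rate: float
    channel_labels: list[str] = field(default_factory=list)
    channel_positions: np.ndarray | None = None
    subject: str | None = None

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be n_epochs x channels x samples")
        if self.epochs.shape[0] != len(self.labels):
            raise ValueError("one label per epoch required")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    def select(self, label: str) -> np.ndarray:
        mask = np.array([lab == label for lab in self.labels])
        return self.epochs[mask]


def _fir_filter(data: np.ndarray, fs: float, *, band: tuple[float, float],
                kind: str, transition: float) -> np.ndarray:
    """Zero-phase windowed-sinc FIR filter along the last axis."""
    nyq = fs / 2.0
    # Hamming window: ~3.3 / normalized transition width taps
    numtaps = int(np.ceil(3.3 * fs / transition))
    if numtaps % 2 == 0:
        numtaps += 1
    low, high = band
    if kind == "bandpass":
        taps = signal.firwin(numtaps, [low, high], pass_zero=False, fs=fs)
    elif kind == "bandstop":
        taps = signal.firwin(numtaps, [low, high], pass_zero=True, fs=fs)
    else:  # pragma: no cover - internal guard
        raise ValueError(kind)
    padlen = min(data.shape[-1] - 1, 3 * numtaps)
    return signal.filtfilt(taps, 1.0, data, axis=-1, padlen=padlen)


def average_reference(data: np.ndarray) -> np.ndarray:
    """Subtract the per-sample channel mean (common average reference)."""
    return data - data.mean(axis=0, keepdims=True)


def _legendre_g(cosang: np.ndarray, stiffness: int = 4, n_terms: int = 20) -> np.ndarray:
    """Perrin spherical-spline kernel g(cos theta)."""
    n = np.arange(1, n_terms + 1)
    coeff = (2 * n + 1) / (n ** stiffness * (n + 1) ** stiffness)
    full = np.zeros(n_terms + 1)
    full[1:] = coeff
    return legendre.legval(np.clip(cosang, -1.0, 1.0), full) / (4 * np.pi)


def spline_interpolate(data: np.ndarray, positions: np.ndarray,
                       bad: np.ndarray, *, reg: float = 1e-5) -> np.ndarray:
    """Replace ``bad`` channels by spherical-spline interpolation from the rest.

    ``positions`` are unit-sphere coordinates; ``bad`` is a boolean mask over
    channels.  Returns a copy of ``data`` with bad rows rebuilt.
    """
    good = ~bad
    n_good = int(good.sum())
    if n_good < 3:
        raise UnrecoverableDataError(
            f"only {n_good} clean channels; cannot interpolate"
        )
    pos_good = positions[good]
    pos_bad = positions[bad]
    G = _legendre_g(pos_good @ pos_good.T)
    G = G + reg * np.eye(n_good)
    # Perrin 1989 system with the zero-sum constraint on spline weights
    A = np.zeros((n_good + 1, n_good + 1))
    A[:n_good, :n_good] = G
    A[:n_good, n_good] = 1.0
    A[n_good, :n_good] = 1.0
    rhs = np.zeros((n_good + 1, data.shape[1]))
    rhs[:n_good] = data[good]
    sol = np.linalg.solve(A, rhs)
    weights, c0 = sol[:n_good], sol[n_good]
    Gb = _legendre_g(pos_bad @ pos_good.T)
    out = data.copy()
    out[bad] = Gb @ weights + c0
    return out


def detect_bad_channels(data: np.ndarray, threshold_uv: float,
                        bad_fraction: float) -> np.ndarray:
    """Boolean mask of channels exceeding ``threshold_uv`` on more than
    ``bad_fraction`` of samples."""
    frac = (np.abs(data) > threshold_uv).mean(axis=1)
    return frac > bad_fraction


def preprocess(rec: EEGRecording, config: PreprocessConfig | None = None) -> EEGRecording:
    """Run the full preprocessing chain; returns a new 19-channel recording.

    Steps: montage selection, resampling, band-stop then band-pass filtering,
    optional artifact hook, average reference, bad-channel interpolation and
    re-referencing.
    """
    config = config or PreprocessConfig()
    missing = [ch for ch in config.channels if ch not in rec.channel_labels]
    if missing:
        raise MontageError(
            f"recording lacks required 10-20 channels: {', '.join(missing)}"
        )
    rec = rec.pick(config.channels)

    data, rate = rec.data, rec.sample_rate
    if abs(rate - config.target_rate) > 1e-9:
        from fractions import Fraction

        frac = Fraction(config.target_rate / rate).limit_denominator(1000)
        data = signal.resample_poly(data, frac.numerator, frac.denominator, axis=-1)
        rate = config.target_rate

    tw = config.transition_bandwidth_hz
    data = _fir_filter(data, rate, band=config.band_stop, kind="bandstop", transition=tw)
    data = _fir_filter(data, rate, band=config.band_pass, kind="bandpass", transition=tw)

    out = replace(rec, data=data, sample_rate=rate)
    if config.artifact_hook is not None:
        out = config.artifact_hook(out)
        data = out.data

    data = average_reference(data)
    bad = detect_bad_channels(data, config.amplitude_threshold_uv, config.bad_fraction)
    if bad.all():
        raise UnrecoverableDataError("every channel exceeds the amplitude threshold")
    if bad.any():
        logger.info("interpolating %d bad channel(s): %s", bad.sum(),
                    [out.channel_labels[i] for i in np.flatnonzero(bad)])
        data = spline_interpolate(data, out.channel_positions, bad)
        data = average_reference(data)

    return replace(out, data=data, sample_rate=rate)


def segment(rec: EEGRecording, epoch_length_s: float,
            labels: "list[tuple[float, float, str]] | None" = None) -> EpochSet:
    """Cut non-overlapping fixed-length epochs inside annotated intervals.

    ``labels`` defaults to ``rec.annotations``; each ``(onset, duration,
    state)`` interval is tiled with contiguous windows from its start, the
    trailing partial window discarded.  Samples outside every interval yield
    no epochs; the count of discarded unlabeled seconds is logged.
    """
    if rec.duration_s < epoch_length_s:
        logger.warning(
            "recording of %.1f s shorter than epoch length %.1f s; empty epoch set",
            rec.duration_s, epoch_length_s,
        )
        return EpochSet(
            epochs=np.empty((0, rec.n_channels, int(round(epoch_length_s * rec.sample_rate)))),
            labels=[],
            epoch_length_s=epoch_length_s,
            sample_rate=rec.sample_rate,
            channel_labels=list(rec.channel_labels),
            channel_positions=rec.channel_positions,
        )

    intervals = labels if labels is not None else rec.annotations
    if not intervals:
        intervals = [(0.0, rec.duration_s, "unlabeled")]
    n_per_epoch = int(round(epoch_length_s * rec.sample_rate))
    chunks, out_labels = [], []
    covered = 0.0
    for onset, duration, state in intervals:
        start = int(round(onset * rec.sample_rate))
        stop = min(int(round((onset + duration) * rec.sample_rate)), rec.n_samples)
        n_epochs = (stop - start) // n_per_epoch
        covered += duration
        for e in range(n_epochs):
            s0 = start + e * n_per_epoch
            chunks.append(rec.data[:, s0 : s0 + n_per_epoch])
            out_labels.append(state)
    uncovered = rec.duration_s - covered
    if uncovered > epoch_length_s:
        logger.info("%.1f s of recording outside annotated intervals excluded", uncovered)
    epochs = np.stack(chunks) if chunks else np.empty((0, rec.n_channels, n_per_epoch))
    return EpochSet(
        epochs=epochs,
        labels=out_labels,
        epoch_length_s=epoch_length_s,
        sample_rate=rec.sample_rate,
        channel_labels=list(rec.channel_labels),
        channel_positions=rec.channel_positions,
    )
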