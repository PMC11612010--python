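"""Synthetic multichannel EEG with planted microstate structure.

The generator emulates the statistical structure microstate analysis
assumes: k smooth, mutually orthogonal scalp topographies alternate
according to a semi-Markov chain (class transitions from a stochastic
matrix, dwell times geometric -- or lognormal behind a flag -- with
controllable means), each topography is amplitude-modulated by a rectified
alpha-band envelope so the GFP oscillates and peaks, band-limited sinusoidal
background and white noise are added at a controllable SNR, and the output
is average-referenced.

Two-class datasets plant class-conditional effects on the "preictal" class:
per-class dwell multipliers (class A up, class C down, matching the
direction of reported preictal microstate shifts), scaling of the delta and
theta background (delta down, theta up preictally), a bias of the
transition matrix toward a deterministic cycle (reducing label-sequence
complexity), and an optional epoch label-noise rate.  Effect magnitudes are
free parameters; :func:`strong_effects` is a preset with deliberately large,
easily separable effects for end-to-end demonstrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import SpecError
from .io import EEGRecording, STANDARD_19, standard_positions
from .preprocess import EpochSet, average_reference

INTERICTAL = "interictal"
PREICTAL = "preictal"


@dataclass
class ClassEffects:
    """Multiplicative/additive effects applied to the preictal class."""

    dwell_multipliers: tuple[float, ...] = (1.5, 1.0, 1 / 1.5, 1.0)
    delta_amplitude_factor: float = 0.7
    theta_amplitude_factor: float = 1.2
    transition_bias: float = 0.3
    label_noise_rate: float = 0.0


def strong_effects() -> ClassEffects:
    """Large planted effects for end-to-end separability demonstrations."""
    return ClassEffects(
        dwell_multipliers=(2.0, 1.0, 0.5, 1.0),
        delta_amplitude_factor=0.5,
        theta_amplitude_factor=1.6,
        transition_bias=0.6,
    )


@dataclass
class SyntheticSpec:
    """Everything needed to reproducibly generate a synthetic recording."""

    n_channels: int = 19
    sample_rate: float = 250.0
    k: int = 4
    templates: np.ndarray | None = None
    transition_matrix: np.ndarray | None = None
    mean_dwell_ms: tuple[float, ...] | None = None
    snr_db: float = 20.0
    template_amplitude_uv: float = 10.0
    envelope_freq_hz: float = 10.0
    envelope_floor: float = 0.25
    oscillations: tuple[tuple[float, float], ...] = (
        (2.5, 4.0), (6.0, 3.0), (10.0, 3.0), (20.0, 1.5),
    )
    dwell_distribution: str = "geometric"  # "geometric" | "lognormal"
    class_effects: ClassEffects = field(default_factory=ClassEffects)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_dwell_ms is None:
            self.mean_dwell_ms = tuple([80.0] * self.k)
        if len(self.mean_dwell_ms) != self.k:
            raise SpecError("need one mean dwell per class")
        if any(d <= 0 for d in self.mean_dwell_ms):
            raise SpecError("mean dwells must be positive")
        if self.transition_matrix is None:
            tm = np.full((self.k, self.k), 1.0 / (self.k - 1))
            np.fill_diagonal(tm, 0.0)
            self.transition_matrix = tm
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        if self.transition_matrix.shape != (self.k, self.k):
            raise SpecError("transition matrix must be k x k")
        if np.any(self.transition_matrix < 0) or not np.allclose(
            self.transition_matrix.sum(axis=1), 1.0
        ):
            raise SpecError("transition matrix rows must be non-negative and sum to 1")
        if self.dwell_distribution not in ("geometric", "lognormal"):
            raise SpecError(f"unknown dwell distribution {self.dwell_distribution!r}")

    @classmethod
    def from_yaml(cls, path) -> "SyntheticSpec":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "class_effects" in raw:
            eff = dict(raw["class_effects"])
            if "dwell_multipliers" in eff:
                eff["dwell_multipliers"] = tuple(eff["dwell_multipliers"])
            raw["class_effects"] = ClassEffects(**eff)
        for key in ("mean_dwell_ms", "oscillations"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(
                    tuple(v) if isinstance(v, (list, tuple)) else v for v in raw[key]
                )
        return cls(**raw)


@dataclass
class GroundTruth:
    """Planted quantities alongside a generated dataset."""

    templates: np.ndarray
    mean_dwell_ms: dict[str, tuple[float, ...]]
    label_sequences: dict[str, np.ndarray]
    epoch_labels: list[str] = field(default_factory=list)
    effects: ClassEffects | None = None


def make_templates(n_channels: int, k: int, *, rng: np.random.Generator,
                   positions: np.ndarray | None = None) -> np.ndarray:
    """k smooth, zero-mean, orthonormal scalp topographies.

    Smoothness comes from evaluating random low-order polynomials of the 3-D
    electrode coordinates; Gram-Schmidt after average-referencing makes the
    maps exactly orthogonal, hence pairwise spatial correlation 0.
    """
    if positions is None:
        if n_channels == len(STANDARD_19):
            positions = standard_positions(STANDARD_19)
        else:
            phi = rng.uniform(0, 2 * np.pi, n_channels)
            theta = rng.uniform(0, np.pi / 2, n_channels)
            positions = np.stack([
                np.sin(theta) * np.cos(phi),
                np.sin(theta) * np.sin(phi),
                np.cos(theta),
            ], axis=1)
    x, y, z = positions.T
    basis = np.stack([x, y, z, x * y, x * z, y * z, x**2 - y**2], axis=1)
    maps = []
    tries = 0
    while len(maps) < k:
        tries += 1
        if tries > 100 * k:
            raise SpecError("could not build enough independent templates")
        v = basis @ rng.normal(size=basis.shape[1])
        v = v - v.mean()
        for m in maps:
            v = v - (v @ m) * m
        nrm = np.linalg.norm(v)
        if nrm < 1e-6:
            continue
        maps.append(v / nrm)
    return np.stack(maps)


def _dwell_samples(mean_samples: float, spec: SyntheticSpec,
                   rng: np.random.Generator) -> int:
    if spec.dwell_distribution == "geometric":
        return int(rng.geometric(min(1.0, 1.0 / mean_samples)))
    # lognormal with sigma 0.5, mean matched
    sigma = 0.5
    mu = np.log(mean_samples) - sigma**2 / 2
    return max(1, int(round(rng.lognormal(mu, sigma))))


def simulate_sequence(spec: SyntheticSpec, duration_s: float, *,
                      rng: np.random.Generator | None = None,
                      mean_dwell_ms: tuple[float, ...] | None = None,
                      transition_matrix: np.ndarray | None = None,
                      ) -> tuple[np.ndarray, GroundTruth]:
    """Semi-Markov microstate label sequence of ``duration_s`` seconds.

    Labels are 1..k; the class path follows the transition matrix and each
    visit dwells for a random number of samples with the planted mean.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    dwells = mean_dwell_ms if mean_dwell_ms is not None else spec.mean_dwell_ms
    tm = transition_matrix if transition_matrix is not None else spec.transition_matrix
    n = int(round(duration_s * spec.sample_rate))
    labels = np.empty(n, dtype=int)
    state = int(rng.integers(spec.k))
    pos = 0
    while pos < n:
        mean_samp = dwells[state] * spec.sample_rate / 1000.0
        d = min(_dwell_samples(mean_samp, spec, rng), n - pos)
        labels[pos : pos + d] = state + 1
        pos += d
        state = int(rng.choice(spec.k, p=tm[state]))
    truth = GroundTruth(
        templates=spec.templates if spec.templates is not None else np.empty(0),
        mean_dwell_ms={"sequence": tuple(dwells)},
        label_sequences={"sequence": labels},
    )
    return labels, truth


def render_eeg(labels: np.ndarray, spec: SyntheticSpec, *,
               rng: np.random.Generator | None = None,
               oscillations: tuple[tuple[float, float], ...] | None = None,
               ) -> EEGRecording:
    """Render a label sequence to an average-referenced multichannel recording.

    Each sample is the labeled template scaled by a rectified-sinusoid
    envelope, plus sinusoidal background (random per-channel phase) and white
    noise scaled to ``snr_db`` relative to the template signal power.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    labels = np.asarray(labels, dtype=int)
    if labels.min() < 1 or (spec.templates is not None and
                            labels.max() > spec.templates.shape[0]):
        raise SpecError("labels must lie in 1..k")
    templates = spec.templates
    if templates is None:
        templates = make_templates(spec.n_channels, spec.k, rng=rng)
    n = labels.size
    t = np.arange(n) / spec.sample_rate
    # rectified sinusoid with a floor: GFP oscillates and peaks but never
    # vanishes, as in real recordings
    envelope = (spec.envelope_floor + (1.0 - spec.envelope_floor)
                * np.abs(np.sin(2 * np.pi * spec.envelope_freq_hz * t)))
    signal = templates[labels - 1].T * envelope * spec.template_amplitude_uv

    osc = oscillations if oscillations is not None else spec.oscillations
    background = np.zeros_like(signal)
    for freq, amp in osc:
        phase = rng.uniform(0, 2 * np.pi, spec.n_channels)
        gain = rng.uniform(0.5, 1.5, spec.n_channels)
        background += amp * gain[:, None] * np.sin(
            2 * np.pi * freq * t[None, :] + phase[:, None]
        )

    data = signal + background
    if np.isfinite(spec.snr_db):
        p_signal = float((signal**2).mean())
        p_noise = p_signal / 10 ** (spec.snr_db / 10.0)
        data = data + rng.normal(scale=np.sqrt(p_noise), size=data.shape)
    data = average_reference(data)
    if spec.n_channels == len(STANDARD_19):
        ch = list(STANDARD_19)
        pos = standard_positions(STANDARD_19)
    else:
        ch = [f"ch{i}" for i in range(spec.n_channels)]
        pos = np.zeros((spec.n_channels, 3))
    return EEGRecording(data=data, sample_rate=spec.sample_rate,
                        channel_labels=ch, channel_positions=pos)


def _apply_effects(spec: SyntheticSpec) -> tuple[tuple[float, ...], np.ndarray,
                                                 tuple[tuple[float, float], ...]]:
    """Preictal dwell means, transition matrix and background amplitudes."""
    eff = spec.class_effects
    mult = list(eff.dwell_multipliers)
    if len(mult) < spec.k:
        mult = mult + [1.0] * (spec.k - len(mult))
    dwells = tuple(d * m for d, m in zip(spec.mean_dwell_ms, mult))
    # bias transitions toward the deterministic cycle 1->2->...->k->1
    cycle = np.zeros((spec.k, spec.k))
    for i in range(spec.k):
        cycle[i, (i + 1) % spec.k] = 1.0
    tm = (1 - eff.transition_bias) * spec.transition_matrix + eff.transition_bias * cycle
    tm = tm / tm.sum(axis=1, keepdims=True)
    osc = []
    for freq, amp in spec.oscillations:
        if freq < 4.0:
            amp = amp * eff.delta_amplitude_factor
        elif freq < 8.0:
            amp = amp * eff.theta_amplitude_factor
        osc.append((freq, amp))
    return dwells, tm, tuple(osc)


def generate_dataset(spec: SyntheticSpec, n_epochs_per_class: int, *,
                     epoch_length_s: float = 3.0,
                     ) -> tuple[EpochSet, GroundTruth]:
    """Balanced two-class epoch set with planted preictal effects.

    Generates one continuous recording per class (interictal with the base
    spec, preictal with the class effects applied), cuts non-overlapping
    epochs and interleaves the two classes.  Fully reproducible from
    ``spec.seed``.
    """
    if n_epochs_per_class < 1:
        raise SpecError("need at least one epoch per class")
    rng = np.random.default_rng(spec.seed)
    templates = spec.templates
    if templates is None:
        templates = make_templates(spec.n_channels, spec.k, rng=rng)
    spec = replace(spec, templates=templates)

    duration = n_epochs_per_class * epoch_length_s
    n_per_epoch = int(round(epoch_length_s * spec.sample_rate))

    pre_dwells, pre_tm, pre_osc = _apply_effects(spec)
    conditions = {
        INTERICTAL: (spec.mean_dwell_ms, spec.transition_matrix, spec.oscillations),
        PREICTAL: (pre_dwells, pre_tm, pre_osc),
    }
    all_epochs, all_labels = [], []
    sequences: dict[str, np.ndarray] = {}
    for condition, (dwells, tm, osc) in conditions.items():
        labels, _ = simulate_sequence(spec, duration, rng=rng,
                                      mean_dwell_ms=dwells, transition_matrix=tm)
        rec = render_eeg(labels, spec, rng=rng, oscillations=osc)
        sequences[condition] = labels
        for e in range(n_epochs_per_class):
            all_epochs.append(rec.data[:, e * n_per_epoch : (e + 1) * n_per_epoch])
            all_labels.append(condition)

    noise_rate = spec.class_effects.label_noise_rate
    if noise_rate > 0:
        flip = rng.random(len(all_labels)) < noise_rate
        all_labels = [
            ({INTERICTAL: PREICTAL, PREICTAL: INTERICTAL}[lab] if f else lab)
            for lab, f in zip(all_labels, flip)
        ]

    epoch_set = EpochSet(
        epochs=np.stack(all_epochs),
        labels=all_labels,
        epoch_length_s=epoch_length_s,
        sample_rate=spec.sample_rate,
        channel_labels=list(STANDARD_19) if spec.n_channels == 19
        else [f"ch{i}" for i in range(spec.n_channels)],
        channel_positions=standard_positions(STANDARD_19)
        if spec.n_channels == 19 else None,
    )
    truth = GroundTruth(
        templates=templates,
        mean_dwell_ms={INTERICTAL: tuple(spec.mean_dwell_ms),
                       PREICTAL: tuple(pre_dwells)},
        label_sequences=sequences,
        epoch_labels=list(all_labels),
        effects=spec.class_effects,
    )
    return epoch_set, truth
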