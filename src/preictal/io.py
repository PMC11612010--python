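"""EDF input/output and the in-memory EEG recording container.

Recordings are kept as plain ``channels x samples`` float arrays in microvolts,
with 10-20 channel names, unit-sphere electrode coordinates and a list of
``(onset_s, duration_s, state_label)`` annotations marking interictal/preictal
intervals.  Reading goes through :func:`mne.io.read_raw_edf`; writing uses a
small built-in EDF+ serializer (16-bit physical scaling, one annotation
channel) so synthetic recordings can round-trip through the clinical format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import EDFReadError

#: The 19 scalp electrodes of the international 10-20 system used throughout.
STANDARD_19 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6", "O1", "O2",
)

# Old (T3/T4/T5/T6) to modern (T7/T8/P7/P8) 10-20 naming.
_MODERN_ALIAS = {"T3": "T7", "T4": "T8", "T5": "P7", "T6": "P8"}


def standard_positions(labels: "list[str] | tuple[str, ...]") -> np.ndarray:
    """Idealized unit-sphere 3D coordinates for 10-20 channel names.

    Uses the mne ``standard_1020`` template montage, projected onto the unit
    sphere around the head origin.  Channels the template does not know get
    NaN coordinates.
    """
    import mne

    try:  # renamed template montage in newer mne versions
        montage = mne.channels.make_standard_montage("colin27_1020")
    except ValueError:
        montage = mne.channels.make_standard_montage("standard_1020")
    pos_map = montage.get_positions()["ch_pos"]
    out = np.full((len(labels), 3), np.nan)
    for i, lab in enumerate(labels):
        name = lab if lab in pos_map else _MODERN_ALIAS.get(lab, lab)
        if name in pos_map:
            p = np.asarray(pos_map[name], dtype=float)
            nrm = np.linalg.norm(p)
            if nrm > 0:
                out[i] = p / nrm
    return out


@dataclass
class EEGRecording:
    """Multichannel scalp EEG: ``data`` is channels x samples in microvolts."""

    data: np.ndarray
    sample_rate: float
    channel_labels: list[str]
    channel_positions: np.ndarray | None = None
    annotations: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples array")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.data.shape[0]} data rows but "
                f"{len(self.channel_labels)} channel labels"
            )
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.channel_positions is None:
            self.channel_positions = standard_positions(self.channel_labels)
        self.channel_positions = np.asarray(self.channel_positions, dtype=float)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    def pick(self, labels: "list[str] | tuple[str, ...]") -> "EEGRecording":
        """Return a copy restricted to ``labels``, in the given order."""
        from .errors import MontageError

        idx = []
        for lab in labels:
            if lab not in self.channel_labels:
                raise MontageError(f"channel {lab!r} not present in recording")
            idx.append(self.channel_labels.index(lab))
        return EEGRecording(
            data=self.data[idx].copy(),
            sample_rate=self.sample_rate,
            channel_labels=list(labels),
            channel_positions=self.channel_positions[idx].copy(),
            annotations=list(self.annotations),
        )


def read_edf(path: "str | Path") -> EEGRecording:
    """Read an EDF/EDF+ file into an :class:`EEGRecording` (microvolts).

    All channels are preserved; montage selection happens later in
    preprocessing.  Annotations are carried over as
    ``(onset_s, duration_s, label)`` tuples.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise EDFReadError(f"EDF file not found: {path}")
    _check_edf_size(path)
    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="ERROR")
    except Exception as exc:  # mne raises a zoo of types for bad files
        raise EDFReadError(f"cannot read EDF file {path}: {exc}") from exc

    data_uv = raw.get_data() * 1e6  # mne loads volts
    labels = list(raw.ch_names)
    annotations = [
        (float(a["onset"]), float(a["duration"]), str(a["description"]))
        for a in raw.annotations
    ]
    return EEGRecording(
        data=data_uv,
        sample_rate=float(raw.info["sfreq"]),
        channel_labels=labels,
        channel_positions=standard_positions(labels),
        annotations=annotations,
    )


def _check_edf_size(path: Path) -> None:
    """Reject files whose size disagrees with the header (truncated data)."""
    size = path.stat().st_size
    if size < 256:
        raise EDFReadError(f"EDF file {path} too small to hold a header")
    with open(path, "rb") as fh:
        head = fh.read(256)
        try:
            header_bytes = int(head[184:192])
            n_records = int(head[236:244])
            n_signals = int(head[252:256])
        except ValueError as exc:
            raise EDFReadError(f"corrupt EDF header in {path}") from exc
        if size < header_bytes:
            raise EDFReadError(f"EDF file {path} truncated inside the header")
        fh.seek(256 + 216 * n_signals)
        spr_field = fh.read(8 * n_signals)
    try:
        spr = [int(spr_field[i * 8 : (i + 1) * 8]) for i in range(n_signals)]
    except ValueError as exc:
        raise EDFReadError(f"corrupt EDF signal header in {path}") from exc
    expected = header_bytes + n_records * 2 * sum(spr)
    if n_records >= 0 and size < expected:
        raise EDFReadError(
            f"EDF file {path} truncated: {size} bytes, header promises {expected}"
        )


def _tal(onset: float, duration: float | None, text: str) -> bytes:
    onset_s = f"{onset:+.4f}".rstrip("0").rstrip(".")
    if "+" not in onset_s and "-" not in onset_s:
        onset_s = "+" + onset_s
    out = onset_s.encode("ascii")
    if duration is not None:
        dur_s = f"{duration:.4f}".rstrip("0").rstrip(".")
        out += b"\x15" + dur_s.encode("ascii")
    out += b"\x14" + text.encode("ascii") + b"\x14\x00"
    return out


def write_edf(rec: EEGRecording, path: "str | Path") -> None:
    """Write a recording as EDF+C with 16-bit samples and one annotation channel.

    The record duration is chosen so every record holds an integer number of
    samples per channel; annotations are serialized as EDF+ time-stamped
    annotation lists.
    """
    path = Path(path)
    rate = rec.sample_rate
    # pick a record duration with integer samples/record (1 s when possible)
    if abs(rate - round(rate)) < 1e-9:
        rec_dur, spr = 1.0, int(round(rate))
    else:
        rec_dur, spr = 2.0, int(round(2 * rate))
        if abs(2 * rate - spr) > 1e-9:
            raise ValueError(f"sample rate {rate} not representable in EDF records")

    n_samp = rec.n_samples
    n_records = int(np.ceil(n_samp / spr))
    pad = n_records * spr - n_samp
    data = rec.data
    if pad:
        data = np.hstack([data, np.tile(data[:, -1:], (1, pad))])

    # physical scaling per channel
    phys_min = np.floor(np.minimum(data.min(axis=1), -1.0))
    phys_max = np.ceil(np.maximum(data.max(axis=1), 1.0))
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((data - phys_min[:, None]) * scale[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    # annotation channel payload: record-start TAL + event TALs (first record)
    events = b"".join(_tal(on, du, lab) for on, du, lab in rec.annotations)
    ann_record_bytes = [_tal(r * rec_dur, None, "") for r in range(n_records)]
    ann_record_bytes[0] += events
    ann_len = max(len(b) for b in ann_record_bytes)
    ann_spr = int(np.ceil(ann_len / 2))  # annotation "samples" are 2 bytes

    n_sig = rec.n_channels + 1
    header_bytes = 256 * (1 + n_sig)

    def _f(value: str, width: int) -> bytes:
        s = value[:width]
        return s.ljust(width).encode("ascii")

    hdr = b""
    hdr += _f("0", 8)
    hdr += _f("X X X X", 80)  # local patient id (anonymous)
    hdr += _f("Startdate X X X X", 80)
    hdr += _f("01.01.00", 8) + _f("00.00.00", 8)
    hdr += _f(str(header_bytes), 8)
    hdr += _f("EDF+C", 44)
    hdr += _f(str(n_records), 8)
    hdr += _f(f"{rec_dur:g}", 8)
    hdr += _f(str(n_sig), 4)

    labels = [lab for lab in rec.channel_labels] + ["EDF Annotations"]
    hdr += b"".join(_f(lab, 16) for lab in labels)
    hdr += b"".join(_f("", 80) for _ in labels)  # transducer
    hdr += b"".join(_f("uV", 8) for _ in rec.channel_labels) + _f("", 8)
    hdr += b"".join(_f(f"{v:g}"[:8], 8) for v in phys_min) + _f("-1", 8)
    hdr += b"".join(_f(f"{v:g}"[:8], 8) for v in phys_max) + _f("1", 8)
    hdr += b"".join(_f(str(dig_min), 8) for _ in labels)
    hdr += b"".join(_f(str(dig_max), 8) for _ in labels)
    hdr += b"".join(_f("", 80) for _ in labels)  # prefiltering
    hdr += b"".join(_f(str(spr), 8) for _ in rec.channel_labels)
    hdr += _f(str(ann_spr), 8)
    hdr += b"".join(_f("", 32) for _ in labels)  # reserved

    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(n_records):
            block = digital[:, r * spr : (r + 1) * spr]
            fh.write(block.tobytes())
            ann = ann_record_bytes[r].ljust(2 * ann_spr, b"\x00")
            fh.write(ann)
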