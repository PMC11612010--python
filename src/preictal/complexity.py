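"""Nonlinear complexity features from voltage signals and microstate sequences.

Two families are provided:

* Lempel-Ziv complexity (LZ76 exhaustive-history parsing) of a binarized EEG
  channel (``lzc``) and of the 4-letter microstate label sequence (``mlzc``).
  A lower count of incompressible words means more repetitive dynamics.
* Permutation entropy of a voltage signal (``perm_entropy``, Shannon entropy
  of ordinal patterns of the delay embedding, normalized by ln(m!)) and its
  microstate analogue (``mperm_entropy``), which first collapses adjacent
  repeats of the label sequence, then tallies each embedded m-tuple against
  the full m^m state-pattern table.

Normalization conventions: LZC divides the word count by N/log2(N); mLZC by
N/log_A(N) with A the alphabet size (configurable back to base 2); mPermEn
divides by ln(m^m) so the value stays in [0, 1] (configurable to ln(m!)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import LengthError, ParameterError
from .microstates import UNASSIGNED, MicrostateSequence

__all__ = [
    "SymbolSequence", "LZCResult", "OrdinalConfig", "PatternDistribution",
    "binarize", "lzc", "mlzc", "perm_entropy", "dedup_adjacent",
    "state_pattern_matrix", "mperm_entropy",
]


@dataclass
class SymbolSequence:
    """A finite-alphabet sequence; symbols are 0-based after remapping."""

    symbols: np.ndarray
    alphabet_size: int

    def __post_init__(self) -> None:
        self.symbols = np.asarray(self.symbols, dtype=int)
        if self.symbols.size and self.symbols.max() >= self.alphabet_size:
            raise ValueError("symbol outside alphabet")
        if self.symbols.size and self.symbols.min() < 0:
            raise ValueError("negative symbol")

    def __len__(self) -> int:
        return int(self.symbols.size)


@dataclass
class LZCResult:
    """LZ76 word count ``pattern_count`` and its length-normalized value."""

    pattern_count: int
    sequence_length: int
    normalized: float


@dataclass
class OrdinalConfig:
    """Delay-embedding parameters: dimension ``m`` and delay ``tau``."""

    embedding_dim: int = 4
    time_delay: int = 1

    def __post_init__(self) -> None:
        if self.embedding_dim < 2:
            raise ParameterError("embedding dimension must be >= 2")
        if self.time_delay < 1:
            raise ParameterError("time delay must be >= 1")


@dataclass
class PatternDistribution:
    """Occurrence counts over a pattern space and their Shannon entropy."""

    counts: np.ndarray
    pattern_space_size: int
    probabilities: np.ndarray
    entropy: float


# ---------------------------------------------------------------------------
# binarization and LZ76


def binarize(signal: np.ndarray, threshold_kind: str = "mean") -> SymbolSequence:
    """Binary-code a signal: 1 where ``x >= Td``, 0 below.

    ``threshold_kind`` selects Td: the mean, the median, or ``mid_p`` (the
    mean of the minimum and maximum).  A constant signal yields all ones
    (the >= convention).
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 2:
        raise LengthError("binarize needs at least 2 samples")
    if threshold_kind == "mean":
        td = x.mean()
    elif threshold_kind == "median":
        td = float(np.median(x))
    elif threshold_kind == "mid_p":
        td = (x.min() + x.max()) / 2.0
    else:
        raise ParameterError(f"unknown threshold kind {threshold_kind!r}")
    return SymbolSequence((x >= td).astype(int), 2)


def lz76_word_count(symbols: np.ndarray) -> int:
    """Number of words in the LZ76 exhaustive-history parsing.

    A word grows while the current word remains a substring of all content
    before its last symbol; otherwise the word is closed and a new one starts.
    The trailing (possibly reproducible) word counts as one word.
    """
    s = bytes(int(v) & 0xFF for v in symbols)
    n = len(s)
    if n == 0:
        raise LengthError("empty sequence")
    count = 0
    i = 0  # start of current word
    while i < n:
        length = 1
        # extend while s[i:i+length] occurs in s[:i+length-1]
        while i + length <= n and s.find(s[i : i + length], 0, i + length - 1) != -1:
            length += 1
        if i + length > n:
            length = n - i  # trailing incomplete word
            count += 1
            break
        count += 1
        i += length
    return count


def lzc(seq: "SymbolSequence | np.ndarray") -> LZCResult:
    """Lempel-Ziv complexity of a binary sequence, normalized by N/log2 N."""
    if not isinstance(seq, SymbolSequence):
        seq = SymbolSequence(np.asarray(seq), 2)
    if seq.alphabet_size != 2:
        raise ParameterError("lzc expects a binary sequence; use mlzc otherwise")
    n = len(seq)
    if n == 0:
        raise LengthError("empty sequence")
    cw = lz76_word_count(seq.symbols)
    norm = cw / (n / np.log2(n)) if n > 1 else float(cw)
    return LZCResult(cw, n, float(norm))


def mlzc(ms_seq: "MicrostateSequence | np.ndarray", *,
         log_base: float | None = None) -> LZCResult:
    """LZ76 complexity of a microstate label sequence.

    Labels must be microstate classes (1..k); unassigned samples must be
    dropped or filled by the caller first.  Normalization divides the word
    count by ``N / log_A(N)`` with ``A`` the alphabet size unless
    ``log_base`` overrides the base (use 2 for the strict binary-style
    normalization).
    """
    if isinstance(ms_seq, MicrostateSequence):
        labels = ms_seq.labels
        k = ms_seq.n_classes
    else:
        labels = np.asarray(ms_seq, dtype=int)
        k = int(labels.max()) if labels.size else 0
    if labels.size == 0:
        raise LengthError("empty sequence")
    if np.any(labels == UNASSIGNED):
        raise ParameterError(
            "mlzc requires a fully assigned sequence; drop or fill unassigned samples"
        )
    n = labels.size
    cw = lz76_word_count(labels)
    base = log_base if log_base is not None else max(k, 2)
    norm = cw / (n / (np.log(n) / np.log(base))) if n > 1 else float(cw)
    return LZCResult(cw, n, float(norm))


# ---------------------------------------------------------------------------
# permutation entropy


def _embed(x: np.ndarray, m: int, tau: int) -> np.ndarray:
    """Delay-embedding matrix R: rows x(k), x(k+tau), ..., x(k+(m-1)tau)."""
    n = x.size
    big_k = n - (m - 1) * tau
    if big_k < 1:
        raise LengthError(
            f"signal of length {n} too short for m={m}, tau={tau}"
        )
    idx = np.arange(big_k)[:, None] + tau * np.arange(m)[None, :]
    return x[idx]


def _shannon(counts: np.ndarray) -> tuple[np.ndarray, float]:
    total = counts.sum()
    p = counts[counts > 0] / total
    return p, float(-(p * np.log(p)).sum())


def perm_entropy(signal: np.ndarray, config: OrdinalConfig | None = None,
                 *, return_distribution: bool = False):
    """Normalized permutation entropy of a voltage signal.

    Each embedding vector is mapped to the permutation that sorts it
    ascending (ties broken by time order, i.e. a stable sort); the Shannon
    entropy of the pattern distribution is divided by ln(m!).  0 for a
    monotone signal, 1 for patterns occurring equally often.
    """
    config = config or OrdinalConfig()
    x = np.asarray(signal, dtype=float)
    m, tau = config.embedding_dim, config.time_delay
    rows = _embed(x, m, tau)
    patterns = np.argsort(rows, axis=1, kind="stable")
    # encode each permutation as an integer in factorial-free base m
    codes = (patterns * (m ** np.arange(m))[None, :]).sum(axis=1)
    _, counts = np.unique(codes, return_counts=True)
    from math import factorial

    p, h = _shannon(counts)
    value = h / np.log(factorial(m))
    if return_distribution:
        dist = PatternDistribution(counts, factorial(m), p, h)
        return float(value), dist
    return float(value)


# ---------------------------------------------------------------------------
# microstate permutation entropy


def dedup_adjacent(ms_seq: "MicrostateSequence | np.ndarray") -> SymbolSequence:
    """Collapse runs of identical adjacent labels to a single symbol.

    The result MS_v satisfies ``ms(u) != ms(u+1)`` everywhere and preserves
    order; applying it twice changes nothing.
    """
    if isinstance(ms_seq, MicrostateSequence):
        labels = ms_seq.labels
        k = ms_seq.n_classes
    else:
        labels = np.asarray(ms_seq, dtype=int)
        k = int(labels.max()) + 1 if labels.size else 1
    if labels.size == 0:
        return SymbolSequence(labels, max(k, 1))
    keep = np.ones(labels.size, dtype=bool)
    keep[1:] = labels[1:] != labels[:-1]
    return SymbolSequence(labels[keep], int(labels.max()) + 1)


def state_pattern_matrix(m: int) -> np.ndarray:
    """The m^m x m table X of all state m-tuples over the alphabet {1..m}.

    Row j (1-based) has entries ``a_jh = ceil(j / m^(m-h)) mod m`` with 0
    remapped to m, which enumerates every tuple exactly once.
    """
    if m < 2:
        raise ParameterError("m must be >= 2")
    j = np.arange(1, m**m + 1)[:, None]
    h = np.arange(1, m + 1)[None, :]
    a = np.ceil(j / m ** (m - h)).astype(int) % m
    a[a == 0] = m
    return a


def _tuple_index(rows: np.ndarray, m: int) -> np.ndarray:
    """0-based row index into ``state_pattern_matrix(m)`` for tuples over {1..m}."""
    weights = m ** np.arange(rows.shape[1] - 1, -1, -1)
    return ((rows - 1) * weights).sum(axis=1)


def mperm_entropy(ms_seq: "MicrostateSequence | np.ndarray",
                  config: OrdinalConfig | None = None, *,
                  normalization: str = "state_space",
                  return_distribution: bool = False):
    """Microstate permutation entropy.

    The label sequence is deduplicated (adjacent repeats removed), embedded
    with dimension ``m`` equal to the number of classes and the given delay,
    and each embedded m-tuple is tallied in the index vector over the full
    m^m state-pattern table.  The Shannon entropy of the tally is divided by
    ln(m^m) (``normalization='state_space'``, keeps the value in [0, 1]) or
    by ln(m!) (``normalization='factorial'``).
    """
    if isinstance(ms_seq, MicrostateSequence):
        if np.any(ms_seq.labels == UNASSIGNED):
            raise ParameterError(
                "mperm_entropy requires a fully assigned sequence"
            )
        m_default = ms_seq.n_classes
        labels = ms_seq.labels
    else:
        labels = np.asarray(ms_seq, dtype=int)
        m_default = int(labels.max()) if labels.size else 2
    config = config or OrdinalConfig(embedding_dim=max(m_default, 2))
    m, tau = config.embedding_dim, config.time_delay
    if labels.size and (labels.min() < 1 or labels.max() > m):
        raise ParameterError(f"labels must lie in 1..{m}")

    dedup = dedup_adjacent(labels).symbols
    need = (m - 1) * tau + 1
    if dedup.size < need:
        raise LengthError(
            f"sequence has only {dedup.size} samples after removing adjacent "
            f"repeats; need at least {need} for m={m}, tau={tau}"
        )
    rows = _embed(dedup, m, tau)
    idx = _tuple_index(rows, m)
    counts = np.bincount(idx, minlength=m**m)
    p, h = _shannon(counts)
    if normalization == "state_space":
        denom = np.log(float(m**m))
    elif normalization == "factorial":
        from math import factorial

        denom = np.log(factorial(m))
    else:
        raise ParameterError(f"unknown normalization {normalization!r}")
    value = h / denom
    if return_distribution:
        dist = PatternDistribution(counts, m**m, p, h)
        return float(value), dist
    return float(value)
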