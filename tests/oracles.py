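"""Independent brute-force oracles used to validate the implementations.

These deliberately avoid the code paths (and even the string-search
primitives) of the package: the LZ76 oracle scans candidate matches with
explicit index loops, and the Wilcoxon oracle enumerates every sign
assignment of the differences.
"""

from __future__ import annotations

from itertools import product

import numpy as np


def lz76_oracle(symbols) -> int:
    """Word count of the LZ76 exhaustive-history parsing.

    A new word is closed as soon as the current word is no longer a
    substring of everything that precedes its final symbol; the trailing
    word counts even if still reproducible.
    """
    s = list(symbols)
    n = len(s)
    assert n > 0
    count = 0
    i = 0
    while i < n:
        length = 1
        while i + length <= n:
            word = s[i : i + length]
            history_end = i + length - 1  # word may overlap itself minus last char
            found = False
            for start in range(0, history_end - length + 1):
                if s[start : start + length] == word:
                    found = True
                    break
            if not found:
                break
            length += 1
        if i + length > n:
            count += 1
            break
        count += 1
        i += length
    return count


def wilcoxon_exact_oracle(diff) -> float:
    """Two-sided exact Wilcoxon signed-rank p by enumerating all 2^n signs.

    Requires nonzero differences with no tied absolute values.  The p-value
    is the standard two-sided exact definition ``min(1, 2*min(P(W <= w),
    P(W >= w)))`` over the uniform sign-flip null.
    """
    diff = np.asarray(diff, dtype=float)
    n = diff.size
    assert np.all(diff != 0)
    ranks = np.argsort(np.argsort(np.abs(diff))) + 1.0
    assert len(set(np.abs(diff))) == n, "oracle requires untied magnitudes"
    w_obs = float(ranks[diff > 0].sum())
    stats = []
    for signs in product((0, 1), repeat=n):
        stats.append(float(sum(r for r, s in zip(ranks, signs) if s)))
    stats = np.asarray(stats)
    p_low = np.mean(stats <= w_obs)
    p_high = np.mean(stats >= w_obs)
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def kruskal_h_oracle(a, b) -> float:
    """Kruskal-Wallis H for two groups by explicit mid-ranking."""
    a = list(map(float, a))
    b = list(map(float, b))
    pooled = sorted(a + b)
    n = len(pooled)

    def midrank(v: float) -> float:
        positions = [i + 1 for i, x in enumerate(pooled) if x == v]
        return sum(positions) / len(positions)

    ra = sum(midrank(v) for v in a)
    rb = sum(midrank(v) for v in b)
    h = 12.0 / (n * (n + 1)) * (ra**2 / len(a) + rb**2 / len(b)) - 3 * (n + 1)
    # tie correction
    from collections import Counter

    ties = Counter(pooled)
    correction = 1.0 - sum(t**3 - t for t in ties.values()) / (n**3 - n)
    return h / correction if correction > 0 else h


def run_lengths_oracle(labels) -> list[tuple[int, int]]:
    """(label, length) runs by a direct scan; used to cross-check parameters."""
    out = []
    labels = list(labels)
    i = 0
    while i < len(labels):
        j = i
        while j < len(labels) and labels[j] == labels[i]:
            j += 1
        out.append((labels[i], j - i))
        i = j
    return out
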