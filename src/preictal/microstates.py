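"""EEG microstate analysis.

A microstate is a quasi-stable scalp potential topography lasting tens of
milliseconds.  This module finds candidate topographies at peaks of the
global field power (GFP), clusters them with the polarity-invariant
Topographic Atomize & Agglomerate Hierarchical Clustering (T-AAHC),
selects the number of classes with a consensus meta-criterion, backfits
templates to continuous data, smooths the resulting label sequence, and
computes the classic temporal parameters (mean duration, time coverage,
occurrence frequency).

Polarity invariance is enforced throughout: topographies are compared by the
absolute spatial Pearson correlation |r|, and cluster centroids are the
dominant eigenvector of the members' outer-product sum, which is sign-free.
The unassigned state is labeled ``0``; microstate classes are ``1..k``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, LengthError, MontageError, ParameterError

logger = logging.getLogger(__name__)

UNASSIGNED = 0


# ---------------------------------------------------------------------------
# global field power


@dataclass
class GFPSeries:
    """Per-sample spatial standard deviation across electrodes, in microvolts."""

    values: np.ndarray
    sample_rate: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def compute_gfp(epoch: np.ndarray, sample_rate: float | None = None) -> GFPSeries:
    """GFP(x) = sqrt( sum_i (V_i - Vbar)^2 / n ) for each sample x."""
    epoch = np.asarray(epoch, dtype=float)
    if epoch.ndim != 2 or epoch.shape[0] < 2:
        raise DegenerateInputError("GFP needs at least 2 channels")
    centered = epoch - epoch.mean(axis=0, keepdims=True)
    return GFPSeries(np.sqrt((centered**2).mean(axis=0)), sample_rate)


def find_gfp_peaks(gfp: GFPSeries) -> np.ndarray:
    """Indices of strict local maxima; endpoints are never peaks."""
    v = gfp.values
    if v.size < 3:
        raise LengthError("need at least 3 samples to find peaks")
    interior = (v[1:-1] > v[:-2]) & (v[1:-1] > v[2:])
    return np.flatnonzero(interior) + 1


# ---------------------------------------------------------------------------
# spatial correlation


def spatial_correlation(map_a: np.ndarray, map_b: np.ndarray) -> tuple[float, float]:
    """Pearson correlation across channels of two average-referenced maps.

    Returns ``(r, |r|)``; the polarity-invariant similarity is ``|r|``.
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise MontageError("maps must share a channel layout with >= 2 channels")
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise DegenerateInputError("zero-variance map has no defined correlation")
    r = float(a @ b / (na * nb))
    return r, abs(r)


def _normalize_maps(maps: np.ndarray) -> np.ndarray:
    """Zero-mean (across channels) unit-norm rows; zero rows stay zero."""
    maps = np.asarray(maps, dtype=float)
    maps = maps - maps.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(maps, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return maps / norms


# ---------------------------------------------------------------------------
# T-AAHC clustering


@dataclass
class MicrostateTemplates:
    """k polarity-free template topographies with their explained variance."""

    maps: np.ndarray  # k x n_channels, zero-mean unit-norm rows
    k: int
    gev: float
    level: str = "individual"  # "individual" | "group"
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.shape[0] != self.k:
            raise ValueError("template count must equal k")

    def to_frame(self):
        import pandas as pd

        cols = self.channel_labels or [f"ch{i}" for i in range(self.maps.shape[1])]
        return pd.DataFrame(self.maps, columns=cols,
                            index=[f"class_{i + 1}" for i in range(self.k)])


class _TAAHCState:
    """Incremental bookkeeping for the atomize-agglomerate loop."""

    def __init__(self, maps_n: np.ndarray, weights: np.ndarray):
        self.maps = maps_n                      # n x ch, zero-mean unit-norm
        self.w = weights                        # gfp^2 per map
        n = maps_n.shape[0]
        self.members: dict[int, list[int]] = {i: [i] for i in range(n)}
        self.centroid: dict[int, np.ndarray] = {i: maps_n[i].copy() for i in range(n)}
        self.scatter: dict[int, np.ndarray] = {
            i: np.outer(maps_n[i], maps_n[i]) for i in range(n)
        }
        self.gev: dict[int, float] = {i: float(weights[i]) for i in range(n)}

    def _update_centroid(self, cid: int) -> None:
        vals, vecs = np.linalg.eigh(self.scatter[cid])
        c = vecs[:, -1]
        c = c - c.mean()
        nrm = np.linalg.norm(c)
        self.centroid[cid] = c / nrm if nrm > 0 else vecs[:, -1]
        idx = self.members[cid]
        corr = self.maps[idx] @ self.centroid[cid]
        self.gev[cid] = float(np.sum(self.w[idx] * corr**2))

    def atomize_step(self) -> None:
        active = sorted(self.members)
        worst = min(active, key=lambda c: (self.gev[c], c))
        freed = self.members.pop(worst)
        self.centroid.pop(worst)
        self.scatter.pop(worst)
        self.gev.pop(worst)
        rest = sorted(self.members)
        cent = np.stack([self.centroid[c] for c in rest])
        absr = np.abs(self.maps[freed] @ cent.T)  # n_freed x n_rest
        target = np.argmax(absr, axis=1)          # ties -> lower index
        changed = set()
        for m, t in zip(freed, target):
            cid = rest[t]
            self.members[cid].append(m)
            self.scatter[cid] += np.outer(self.maps[m], self.maps[m])
            changed.add(cid)
        for cid in changed:
            self._update_centroid(cid)

    def snapshot(self, level: str, channel_labels: list[str]) -> MicrostateTemplates:
        order = sorted(self.members, key=lambda c: -self.gev[c])
        maps = np.stack([self.centroid[c] for c in order])
        gev = float(sum(self.gev.values()) / self.w.sum())
        return MicrostateTemplates(
            maps=maps, k=len(order), gev=gev, level=level,
            channel_labels=channel_labels,
        )

    @property
    def n_clusters(self) -> int:
        return len(self.members)

    def unexplained(self) -> float:
        return float(self.w.sum() - sum(self.gev.values()))


def taahc_cluster(maps: np.ndarray, k: int, *, weights: np.ndarray | None = None,
                  level: str = "individual",
                  channel_labels: list[str] | None = None) -> MicrostateTemplates:
    """Cluster peak topographies into ``k`` classes by T-AAHC.

    Starts from singleton clusters and repeatedly dissolves the cluster
    contributing least GFP-weighted explained variance, reassigning each
    freed map to the centroid of highest ``|r|``, until ``k`` clusters
    remain.  ``weights`` default to the squared GFP of each map.
    """
    maps = np.asarray(maps, dtype=float)
    if k < 1 or k > maps.shape[0]:
        raise ParameterError(f"k={k} outside [1, {maps.shape[0]}]")
    if weights is None:
        weights = (maps - maps.mean(axis=1, keepdims=True)).var(axis=1)
    weights = np.asarray(weights, dtype=float)
    state = _TAAHCState(_normalize_maps(maps), weights)
    while state.n_clusters > k:
        state.atomize_step()
    return state.snapshot(level, channel_labels or [])


def fit_templates_from_epochs(epochs, k: int = 4, *, max_maps: int = 3000,
                              random_state: int | None = 0,
                              level: str = "group") -> MicrostateTemplates:
    """Convenience: pool an epoch set, take GFP-peak maps and T-AAHC them.

    ``epochs`` is an :class:`~preictal.preprocess.EpochSet`.  GFP-peak
    topographies are pooled over all epochs and subsampled to ``max_maps``
    (without replacement, seeded) before clustering, which bounds the
    clustering cost on long recordings.
    """
    data = np.hstack(list(epochs.epochs))
    gfp = compute_gfp(data, epochs.sample_rate)
    peaks = find_gfp_peaks(gfp)
    if peaks.size > max_maps:
        rng = np.random.default_rng(random_state)
        peaks = np.sort(rng.choice(peaks, max_maps, replace=False))
    return taahc_cluster(data[:, peaks].T, k, weights=gfp.values[peaks] ** 2,
                         level=level, channel_labels=list(epochs.channel_labels))


def group_templates(individual: "list[MicrostateTemplates]", k: int = 4) -> MicrostateTemplates:
    """Group-level templates: T-AAHC over all individual template maps, fixed k."""
    maps = np.vstack([t.maps for t in individual])
    labels = individual[0].channel_labels if individual else []
    out = taahc_cluster(maps, k, weights=np.ones(maps.shape[0]),
                        level="group", channel_labels=labels)
    return out


# ---------------------------------------------------------------------------
# meta-criterion for the number of classes


def _silhouette(maps_n: np.ndarray, assignment: np.ndarray) -> float:
    from sklearn.metrics import silhouette_score

    dist = 1.0 - np.abs(maps_n @ maps_n.T)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    if len(np.unique(assignment)) < 2:
        return -1.0
    return float(silhouette_score(dist, assignment, metric="precomputed"))


def select_optimal_k(maps: np.ndarray, k_range: tuple[int, int] = (3, 8), *,
                     weights: np.ndarray | None = None,
                     max_silhouette_maps: int = 1200,
                     random_state: int | None = 0,
                     channel_labels: list[str] | None = None,
                     ) -> tuple[int, dict[int, MicrostateTemplates]]:
    """Fit every k in ``k_range`` and pick the consensus-best class count.

    The meta-criterion is the median rank over three normalized criteria:
    the GEV elbow (largest drop in marginal explained variance), a
    polarity-invariant silhouette with distance ``1 - |r|``, and a
    Krzanowski-Lai-style dispersion ratio.  Ranks are computed over the
    requested range; the hierarchy is fitted once over an extended range so
    boundary values remain eligible.
    """
    maps = np.asarray(maps, dtype=float)
    k_min, k_max = k_range
    if k_min < 1 or k_max < k_min:
        raise ParameterError(f"bad k range {k_range}")
    if maps.shape[0] < k_max + 1:
        raise ParameterError("not enough maps for the requested k range")
    if weights is None:
        weights = (maps - maps.mean(axis=1, keepdims=True)).var(axis=1)
    weights = np.asarray(weights, dtype=float)
    maps_n = _normalize_maps(maps)

    # degenerate input: all maps the same topography (up to sign)
    absr_to_first = np.abs(maps_n @ maps_n[0])
    if np.all(absr_to_first > 1 - 1e-9):
        warnings.warn("all input maps identical; returning minimum k", stacklevel=2)
        templates = taahc_cluster(maps, k_min, weights=weights,
                                  channel_labels=channel_labels)
        return k_min, {k_min: templates}

    lo = max(2, k_min - 1)
    hi = min(maps.shape[0], k_max + 1)
    state = _TAAHCState(maps_n, weights)
    snaps: dict[int, MicrostateTemplates] = {}
    unexplained: dict[int, float] = {}
    while state.n_clusters > lo:
        state.atomize_step()
        kk = state.n_clusters
        if lo <= kk <= hi:
            snaps[kk] = state.snapshot("individual", channel_labels or [])
            unexplained[kk] = state.unexplained()
    ks = [k for k in range(k_min, k_max + 1) if k in snaps]
    if not ks:
        raise ParameterError("no feasible k in range")

    gev = {k: snaps[k].gev for k in snaps}
    # criterion 1: GEV elbow -- marginal gain drop (needs both neighbors)
    elbow = {}
    for k in ks:
        if (k - 1) in gev and (k + 1) in gev:
            elbow[k] = (gev[k] - gev[k - 1]) - (gev[k + 1] - gev[k])
        else:
            elbow[k] = -np.inf

    # criterion 2: silhouette with 1 - |r| distance, on a subsample
    rng = np.random.default_rng(random_state)
    if maps_n.shape[0] > max_silhouette_maps:
        sub = rng.choice(maps_n.shape[0], max_silhouette_maps, replace=False)
    else:
        sub = np.arange(maps_n.shape[0])
    sil = {}
    for k in ks:
        absr = np.abs(maps_n[sub] @ snaps[k].maps.T)
        sil[k] = _silhouette(maps_n[sub], np.argmax(absr, axis=1))

    # criterion 3: Krzanowski-Lai ratio on GFP-weighted unexplained variance
    p = maps.shape[1] - 1  # dimensionality after average reference
    diff = {}
    for k in range(max(lo + 1, 2), hi + 1):
        if (k - 1) in unexplained and k in unexplained:
            diff[k] = ((k - 1) ** (2 / p) * unexplained[k - 1]
                       - k ** (2 / p) * unexplained[k])
    kl = {}
    for k in ks:
        if k in diff and (k + 1) in diff and abs(diff[k + 1]) > 1e-300:
            kl[k] = abs(diff[k]) / abs(diff[k + 1])
        else:
            kl[k] = -np.inf

    def ranks(scores: dict[int, float]) -> dict[int, float]:
        order = sorted(ks, key=lambda k: -scores[k])
        return {k: order.index(k) + 1.0 for k in ks}

    r1, r2, r3 = ranks(elbow), ranks(sil), ranks(kl)
    median_rank = {k: float(np.median([r1[k], r2[k], r3[k]])) for k in ks}
    best = min(ks, key=lambda k: (median_rank[k], k))
    logger.debug("meta-criterion ranks: elbow=%s sil=%s kl=%s -> k=%d",
                 r1, r2, r3, best)
    return best, {k: snaps[k] for k in ks}


# ---------------------------------------------------------------------------
# backfitting, smoothing, parameters


@dataclass
class MicrostateSequence:
    """Per-sample microstate labels (0 = unassigned, 1..k) and best |r|."""

    labels: np.ndarray
    correlations: np.ndarray
    sample_rate: float
    n_classes: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.correlations = np.asarray(self.correlations, dtype=float)
        if self.labels.shape != self.correlations.shape:
            raise ValueError("labels and correlations must align")


def backfit(templates: MicrostateTemplates, epoch: np.ndarray, *,
            sample_rate: float, min_corr: float = 0.5) -> MicrostateSequence:
    """Label every sample with the template of highest ``|r|``.

    The epoch is first normalized by its median GFP at GFP peaks (a per-epoch
    gain correction for skull-conductivity differences); samples whose best
    ``|r|`` falls below ``min_corr`` are left unassigned.
    """
    epoch = np.asarray(epoch, dtype=float)
    if epoch.shape[0] != templates.maps.shape[1]:
        raise MontageError(
            f"epoch has {epoch.shape[0]} channels, templates expect "
            f"{templates.maps.shape[1]}"
        )
    gfp = compute_gfp(epoch, sample_rate)
    try:
        peaks = find_gfp_peaks(gfp)
    except LengthError:
        peaks = np.array([], dtype=int)
    ref = np.median(gfp.values[peaks]) if peaks.size else np.median(gfp.values)
    if ref > 0:
        epoch = epoch / ref

    samples = _normalize_maps(epoch.T)  # n_samples x channels
    corr = samples @ templates.maps.T
    absr = np.abs(corr)
    best = np.argmax(absr, axis=1)
    best_r = absr[np.arange(absr.shape[0]), best]
    labels = best + 1
    labels[best_r < min_corr] = UNASSIGNED
    return MicrostateSequence(labels, best_r, sample_rate, templates.k)


def _runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """(label, start, length) runs of a label sequence."""
    out = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            out.append((int(labels[start]), start, i - start))
            start = i
    return out


def smooth_sequence(seq: MicrostateSequence, min_duration_ms: float = 32.0,
                    max_iter: int | None = None) -> MicrostateSequence:
    """Dissolve runs shorter than ``min_duration_ms`` into their neighbors.

    A short run is halved: the first ``ceil(n/2)`` samples take the preceding
    run's class, the rest the following run's class.  A boundary run (no
    neighbor on one side) goes wholly to its single neighbor.  The unassigned
    state acts as a run class that can donate but never absorb: halves whose
    would-be recipient is unassigned keep their original label.  The rule is
    iterated to a fixed point.
    """
    min_samples = int(round(min_duration_ms * seq.sample_rate / 1000.0))
    labels = seq.labels.copy()
    if max_iter is None:
        max_iter = len(labels) + 1
    for _ in range(max_iter):
        runs = _runs(labels)
        new = labels.copy()
        changed = False
        for idx, (lab, start, length) in enumerate(runs):
            if length >= min_samples:
                continue
            prev_lab = runs[idx - 1][0] if idx > 0 else None
            next_lab = runs[idx + 1][0] if idx < len(runs) - 1 else None
            first = int(np.ceil(length / 2))
            if prev_lab is None and next_lab is None:
                continue
            if prev_lab is None:
                if next_lab != UNASSIGNED:
                    new[start : start + length] = next_lab
                    changed = True
                continue
            if next_lab is None:
                if prev_lab != UNASSIGNED:
                    new[start : start + length] = prev_lab
                    changed = True
                continue
            if prev_lab != UNASSIGNED and prev_lab != lab:
                new[start : start + first] = prev_lab
                changed = True
            if next_lab != UNASSIGNED and next_lab != lab:
                new[start + first : start + length] = next_lab
                changed = True
        if not changed:
            break
        if np.array_equal(new, labels):
            break
        labels = new
    return MicrostateSequence(labels, seq.correlations, seq.sample_rate, seq.n_classes)


@dataclass
class MicrostateParameters:
    """Per-class temporal statistics of a microstate sequence."""

    mean_duration_ms: np.ndarray   # per class 1..k
    coverage_fraction: np.ndarray  # per class 1..k
    occurrence_per_s: np.ndarray   # per class 1..k
    unassigned_fraction: float
    n_classes: int
    missing_classes: list[int] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "class": np.arange(1, self.n_classes + 1),
            "mean_duration_ms": self.mean_duration_ms,
            "coverage_fraction": self.coverage_fraction,
            "occurrence_per_s": self.occurrence_per_s,
        })


def microstate_parameters(seq: MicrostateSequence) -> MicrostateParameters:
    """Mean duration (ms), time coverage and occurrence rate (1/s) per class."""
    labels = seq.labels
    if labels.size == 0:
        raise LengthError("empty microstate sequence")
    n = labels.size
    total_s = n / seq.sample_rate
    runs = _runs(labels)
    k = seq.n_classes
    dur = np.zeros(k)
    cov = np.zeros(k)
    occ = np.zeros(k)
    missing = []
    for c in range(1, k + 1):
        lens = [length for lab, _, length in runs if lab == c]
        cov[c - 1] = labels[labels == c].size / n
        if lens:
            dur[c - 1] = float(np.mean(lens)) / seq.sample_rate * 1000.0
            occ[c - 1] = len(lens) / total_s
        else:
            missing.append(c)
            logger.debug("class %d absent from sequence; duration/occurrence 0", c)
    unassigned = labels[labels == UNASSIGNED].size / n
    return MicrostateParameters(dur, cov, occ, unassigned, k, missing)


def global_explained_variance(templates: MicrostateTemplates,
                              epoch: np.ndarray,
                              seq: MicrostateSequence | None = None) -> float:
    """GFP-weighted fraction of variance explained by the assigned templates."""
    epoch = np.asarray(epoch, dtype=float)
    gfp2 = compute_gfp(epoch).values ** 2
    samples = _normalize_maps(epoch.T)
    corr = np.abs(samples @ templates.maps.T)
    if seq is None:
        r = corr.max(axis=1)
        assigned = np.ones(r.shape, dtype=bool)
    else:
        lab = seq.labels
        assigned = lab != UNASSIGNED
        r = np.zeros(lab.shape)
        r[assigned] = corr[np.arange(len(lab))[assigned], lab[assigned] - 1]
    denom = gfp2.sum()
    if denom == 0:
        raise DegenerateInputError("zero-variance epoch has no defined GEV")
    return float((gfp2[assigned] * r[assigned] ** 2).sum() / denom)
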