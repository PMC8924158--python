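"""ERP contrasts on isolated test words and cluster-based permutation statistics.

The permutation scheme is the standard exact one for paired designs: per
(channel, time) paired t-values are thresholded at a two-sided alpha, adjacent
suprathreshold points of equal polarity are clustered over the electrode
neighborhood graph and temporal contiguity, cluster mass is the summed t, and
the null distribution is the maximum absolute cluster mass under random
within-subject sign flips of the paired differences.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components

from .entrainment import SubjectExcludedError
from .preprocess import EpochSet
from .simulate import MontageSpec

__all__ = [
    "ContrastSpec",
    "CONTRASTS",
    "AdjacencyGraph",
    "ClusterResult",
    "build_adjacency",
    "subject_condition_erps",
    "side_average",
    "cluster_permutation",
    "block_time_course",
    "clusters_frame",
]

logger = logging.getLogger(__name__)

DEFAULT_WINDOWS = ((0.0, 0.5), (0.5, 2.75))


@dataclass(frozen=True)
class ContrastSpec:
    """A partition of the four test conditions into two disjoint sides."""

    name: str
    side_a: tuple[str, ...]
    side_b: tuple[str, ...]
    windows: tuple[tuple[float, float], ...] = DEFAULT_WINDOWS

    def __post_init__(self) -> None:
        if set(self.side_a) & set(self.side_b):
            raise ValueError("contrast sides must be disjoint")


CONTRASTS = {
    "abx-bcx": ContrastSpec("abx-bcx", ("Word", "EdgeWord"), ("PartWord", "NonWord")),
    "heard-unheard": ContrastSpec(
        "heard-unheard", ("Word", "PartWord"), ("EdgeWord", "NonWord")
    ),
    "word-edge": ContrastSpec("word-edge", ("Word",), ("EdgeWord",)),
    "part-non": ContrastSpec("part-non", ("PartWord",), ("NonWord",)),
}


@dataclass(frozen=True)
class AdjacencyGraph:
    """Symmetric electrode neighborhood graph (no self-edges)."""

    channels: tuple[str, ...]
    matrix: np.ndarray  # (n, n) bool
    max_dist: float

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape[0] != m.shape[1] or not np.array_equal(m, m.T) or m.diagonal().any():
            raise ValueError("adjacency must be square, symmetric, and hollow")

    @property
    def mean_degree(self) -> float:
        return float(self.matrix.sum(axis=1).mean())


def build_adjacency(montage: MontageSpec, max_dist: float = 3.0) -> AdjacencyGraph:
    """Neighbor electrodes are those within ``max_dist`` cm (Euclidean)."""
    d = montage.distances()
    mat = d <= max_dist
    np.fill_diagonal(mat, False)
    isolated = np.flatnonzero(~mat.any(axis=1))
    if isolated.size:
        logger.warning(
            "%d isolated channels in adjacency (max_dist=%.1f cm): %s",
            isolated.size, max_dist, [montage.channels[i] for i in isolated],
        )
    return AdjacencyGraph(channels=montage.channels, matrix=mat, max_dist=max_dist)


def subject_condition_erps(
    epochs: EpochSet, conditions: tuple[str, ...], min_trials: int = 12
) -> dict[str, np.ndarray]:
    """Average retained trials per condition for one subject.

    Raises :class:`SubjectExcludedError` when any requested condition has
    fewer than ``min_trials`` retained trials.
    """
    out: dict[str, np.ndarray] = {}
    for cond in conditions:
        mask = (epochs.metadata["condition"] == cond).to_numpy()
        n = int(mask.sum())
        if n < min_trials:
            raise SubjectExcludedError(
                f"condition {cond}: {n} trials retained (minimum {min_trials})"
            )
        out[cond] = epochs.data[mask].mean(axis=0)
    return out


def side_average(erps: dict[str, np.ndarray], side: tuple[str, ...]) -> np.ndarray:
    """Unweighted mean of per-condition ERPs over one contrast side."""
    return np.mean([erps[c] for c in side], axis=0)


@dataclass
class ClusterResult:
    """One spatio-temporal cluster with its permutation p-value."""

    channel_indices: np.ndarray
    time_indices: np.ndarray  # sample indices into the searched window
    polarity: int  # +1 or -1
    mass: float
    p_value: float
    window: tuple[float, float]
    times: np.ndarray  # seconds, aligned with time_indices

    @property
    def size(self) -> int:
        return len(self.channel_indices)

    @property
    def time_extent(self) -> tuple[float, float]:
        return float(self.times.min()), float(self.times.max())


def _edge_arrays(adjacency: np.ndarray, n_times: int) -> tuple[np.ndarray, np.ndarray]:
    """Undirected edge list over the (channel, time) lattice, flat-indexed."""
    n_ch = adjacency.shape[0]
    ci, cj = np.nonzero(np.triu(adjacency, 1))
    t = np.arange(n_times)
    # spatial edges at equal time
    src_sp = (ci[:, None] * n_times + t[None, :]).ravel()
    dst_sp = (cj[:, None] * n_times + t[None, :]).ravel()
    # temporal edges within a channel
    c = np.arange(n_ch)
    src_t = (c[:, None] * n_times + t[None, :-1]).ravel()
    dst_t = src_t + 1
    return np.r_[src_sp, src_t], np.r_[dst_sp, dst_t]


def _clusters_from_tmap(
    tmap: np.ndarray,
    threshold: float,
    edges: tuple[np.ndarray, np.ndarray],
    min_size: int,
    min_size_unit: str,
) -> list[tuple[np.ndarray, int, float]]:
    """Connected suprathreshold clusters: (flat point indices, polarity, mass)."""
    n_ch, n_t = tmap.shape
    flat = tmap.ravel()
    out = []
    for pol in (1, -1):
        mask = (pol * flat) > threshold
        if not mask.any():
            continue
        src, dst = edges
        keep = mask[src] & mask[dst]
        n = flat.size
        g = sparse.coo_matrix(
            (np.ones(keep.sum(), dtype=np.int8), (src[keep], dst[keep])), shape=(n, n)
        )
        _, labels = connected_components(g, directed=False)
        pts = np.flatnonzero(mask)
        for lab in np.unique(labels[pts]):
            members = pts[labels[pts] == lab]
            if min_size_unit == "channels":
                size = len(np.unique(members // n_t))
            else:
                size = len(members)
            if size < min_size:
                continue
            out.append((members, pol, float(flat[members].sum())))
    return out


def _paired_t(diffs: np.ndarray, signs: np.ndarray | None = None) -> np.ndarray:
    """Per-point one-sample t of (optionally sign-flipped) paired differences."""
    d = diffs if signs is None else diffs * signs[:, None, None]
    n = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[~np.isfinite(t)] = 0.0  # zero-variance points carry no cluster evidence
    return t


def cluster_permutation(
    erps_side_a: np.ndarray,
    erps_side_b: np.ndarray,
    adjacency: AdjacencyGraph,
    times: np.ndarray,
    window: tuple[float, float],
    alpha: float = 0.05,
    min_size: int = 2,
    n_perm: int = 5000,
    seed: int = 0,
    min_size_unit: str = "points",
    exact: bool = False,
) -> list[ClusterResult]:
    """Spatio-temporal cluster permutation test on paired subject ERPs.

    Parameters
    ----------
    erps_side_a, erps_side_b:
        (subjects, channels, samples) per-subject condition-side averages,
        paired along the first axis.
    times:
        Sample times in seconds (length = samples).
    window:
        ``(start, end)`` seconds; only samples inside are searched.
    alpha:
        Two-sided point-level threshold used for clustering.
    min_size:
        Minimum cluster size, counted in (channel, time) points by default or
        in distinct channels with ``min_size_unit="channels"``.
    exact:
        Enumerate all ``2**n_subjects`` sign patterns instead of sampling
        ``n_perm`` random ones (small cohorts only); p-values then equal the
        exact permutation fractions.
    """
    a = np.asarray(erps_side_a, float)
    b = np.asarray(erps_side_b, float)
    if a.shape != b.shape:
        raise ValueError("the two sides must have identical shape")
    n_sub = a.shape[0]
    if n_sub < 2:
        raise ValueError("cluster permutation needs at least 2 subjects")
    sel = (times >= window[0]) & (times <= window[1])
    if not sel.any():
        raise ValueError(f"window {window} outside epoch span")
    wtimes = times[sel]
    diffs = (a - b)[:, :, sel]
    n_t = diffs.shape[2]

    threshold = stats.t.ppf(1 - alpha / 2, df=n_sub - 1)
    edges = _edge_arrays(adjacency.matrix, n_t)

    observed = _clusters_from_tmap(
        _paired_t(diffs), threshold, edges, min_size, min_size_unit
    )
    if not observed:
        return []

    if exact:
        if n_sub > 16:
            raise ValueError("exact enumeration is limited to 16 subjects")
        sign_sets = (
            np.array(bits) * 2.0 - 1.0
            for bits in itertools.product((0, 1), repeat=n_sub)
        )
        null_list = []
        for signs in sign_sets:
            perm = _clusters_from_tmap(
                _paired_t(diffs, signs), threshold, edges, min_size, min_size_unit
            )
            null_list.append(max((abs(m) for _, _, m in perm), default=0.0))
        null = np.array(null_list)
        denom = len(null)
        add_one = 0
    else:
        rng = np.random.default_rng(seed)
        null = np.zeros(n_perm)
        for p in range(n_perm):
            signs = rng.choice([-1.0, 1.0], size=n_sub)
            perm = _clusters_from_tmap(
                _paired_t(diffs, signs), threshold, edges, min_size, min_size_unit
            )
            if perm:
                null[p] = max(abs(m) for _, _, m in perm)
        denom = n_perm + 1
        add_one = 1

    results = []
    for members, pol, mass in observed:
        pval = (add_one + np.sum(null >= abs(mass) - 1e-12)) / denom
        results.append(
            ClusterResult(
                channel_indices=members // n_t,
                time_indices=members % n_t,
                polarity=pol,
                mass=mass,
                p_value=float(pval),
                window=tuple(window),
                times=wtimes[members % n_t],
            )
        )
    results.sort(key=lambda c: c.p_value)
    return results


def block_time_course(
    subject_epochs: list[EpochSet],
    contrast: ContrastSpec,
    cluster: ClusterResult,
    min_trials_per_block: int = 3,
    n_blocks: int = 8,
) -> pd.DataFrame:
    """Per-block effect sizes over one cluster's points.

    For every subject and block, the mean difference (side A - side B) over
    the cluster's (channel, time) points is computed; a subject-block cell is
    included only when both sides retain at least ``min_trials_per_block``
    trials in that block.  Returns subject rows plus per-block group mean and
    standard error.
    """
    window = cluster.window
    rows = []
    for s, ep in enumerate(subject_epochs):
        times = ep.times
        sel = np.flatnonzero((times >= window[0]) & (times <= window[1]))
        pt_samples = sel[cluster.time_indices]
        for block in range(1, n_blocks + 1):
            in_block = (ep.metadata["block"] == block).to_numpy()
            mask_a = in_block & ep.metadata["condition"].isin(contrast.side_a).to_numpy()
            mask_b = in_block & ep.metadata["condition"].isin(contrast.side_b).to_numpy()
            if mask_a.sum() < min_trials_per_block or mask_b.sum() < min_trials_per_block:
                continue
            erp_a = ep.data[mask_a].mean(axis=0)
            erp_b = ep.data[mask_b].mean(axis=0)
            diff = erp_a - erp_b
            effect = diff[cluster.channel_indices, pt_samples].mean()
            rows.append({"subject": s, "block": block, "effect": float(effect)})
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    group = (
        df.groupby("block")["effect"]
        .agg(mean="mean", sem=lambda x: x.std(ddof=1) / np.sqrt(len(x)), n="count")
        .reset_index()
    )
    return df.merge(group, on="block", suffixes=("", "_group"))


def clusters_frame(
    clusters: list[ClusterResult], channels: tuple[str, ...]
) -> pd.DataFrame:
    """Cluster report table (id, polarity, p, mass, window, channels, extent)."""
    rows = []
    for i, c in enumerate(clusters):
        rows.append(
            {
                "cluster_id": i,
                "polarity": "pos" if c.polarity > 0 else "neg",
                "p_value": c.p_value,
                "t_mass": c.mass,
                "window_start_s": c.window[0],
                "window_end_s": c.window[1],
                "time_min_s": c.time_extent[0],
                "time_max_s": c.time_extent[1],
                "n_points": c.size,
                "channels": ",".join(
                    channels[j] for j in sorted(set(c.channel_indices.tolist()))
                ),
            }
        )
    return pd.DataFrame(rows)
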