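"""Discrete structural states from trajectory windows.

The trajectory is cut into fixed-length windows; each window is summarised by
the empirical distribution of centroid-referenced agent positions (one CDF
per axis); windows are compared with the 1-D Kantorovich (Wasserstein-1)
distance summed over axes and grouped by average-linkage agglomerative
clustering cut at a distance threshold.  Cluster labels form the state
sequence consumed by the landscape and information-metric stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .trajio import Trajectory

__all__ = [
    "WindowSpec",
    "ECDF",
    "WindowDistribution",
    "StateAssignment",
    "segment",
    "window_distribution",
    "global_distribution",
    "kantorovich",
    "window_distance",
    "pairwise_distances",
    "default_threshold",
    "cluster_windows",
    "escape_times",
    "extract_states",
]


@dataclass(frozen=True)
class WindowSpec:
    """Window length ``delta`` and hop between window starts, in frames.

    ``hop`` defaults to ``delta`` (non-overlapping windows): overlapping
    windows share frames and would inflate self-transition counts downstream.
    """

    delta: int
    hop: int | None = None

    def __post_init__(self) -> None:
        if self.delta < 2:
            raise ValueError("delta must be >= 2")
        hop = self.delta if self.hop is None else self.hop
        if not 1 <= hop <= self.delta:
            raise ValueError("hop must satisfy 1 <= hop <= delta")
        object.__setattr__(self, "hop", hop)


class ECDF:
    """Empirical CDF of a weighted sample, stored as sorted atoms.

    ``values`` are the sorted support points; ``weights`` the matching
    probabilities (summing to 1).  Duplicate atoms are merged.
    """

    __slots__ = ("values", "weights", "cum")

    def __init__(self, samples: np.ndarray, weights: np.ndarray | None = None):
        samples = np.asarray(samples, dtype=float).ravel()
        if samples.size == 0:
            raise ValueError("ECDF requires at least one sample")
        if weights is None:
            weights = np.full(samples.size, 1.0 / samples.size)
        else:
            weights = np.asarray(weights, dtype=float).ravel()
            if weights.shape != samples.shape:
                raise ValueError("weights must match samples")
            total = weights.sum()
            if total <= 0:
                raise ValueError("weights must have positive sum")
            weights = weights / total
        order = np.argsort(samples, kind="stable")
        v, w = samples[order], weights[order]
        uniq, inverse = np.unique(v, return_inverse=True)
        merged = np.zeros(uniq.size)
        np.add.at(merged, inverse, w)
        self.values = uniq
        self.weights = merged
        self.cum = np.cumsum(merged)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        """Evaluate F(x) = P[X <= x]."""
        idx = np.searchsorted(self.values, np.asarray(x, dtype=float), side="right")
        cdf = np.concatenate([[0.0], self.cum])
        return cdf[idx]

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, ECDF)
            and np.array_equal(self.values, other.values)
            and np.allclose(self.weights, other.weights, atol=1e-15)
        )


@dataclass
class WindowDistribution:
    """Per-axis empirical CDFs of the pooled, centroid-referenced agent
    positions inside one window."""

    window_index: int
    center_time: float
    cdfs: tuple[ECDF, ECDF, ECDF]


@dataclass
class StateAssignment:
    """Per-window state labels (1..K, state 1 most populous) with the
    distance matrix and threshold that produced them."""

    labels: np.ndarray
    K: int
    window_spec: WindowSpec
    distances: np.ndarray
    threshold: float
    center_times: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.center_times is None:
            self.center_times = np.arange(len(self.labels), dtype=float)


def segment(traj: Trajectory, spec: WindowSpec) -> list[tuple[int, int]]:
    """Half-open frame ranges ``[start, start + delta)`` advancing by ``hop``;
    trailing frames that cannot fill a window are dropped."""
    T = traj.n_frames
    if T < spec.delta:
        raise ValueError(f"trajectory has {T} frames; window needs {spec.delta}")
    return [(s, s + spec.delta) for s in range(0, T - spec.delta + 1, spec.hop)]


def _pooled_centered(traj: Trajectory, window: tuple[int, int]) -> np.ndarray:
    start, stop = window
    block = traj.positions[start:stop]  # (delta, n, 3)
    centered = block - block.mean(axis=1, keepdims=True)  # per-frame centroid
    return centered.reshape(-1, 3)


def window_distribution(traj: Trajectory, window: tuple[int, int], index: int = 0) -> WindowDistribution:
    """Pool all agent positions in the window, subtract each frame's group
    centroid, and build one empirical CDF per axis."""
    pooled = _pooled_centered(traj, window)
    start, stop = window
    t_c = float(traj.times[start:stop].mean())
    cdfs = tuple(ECDF(pooled[:, k]) for k in range(3))
    return WindowDistribution(window_index=index, center_time=t_c, cdfs=cdfs)  # type: ignore[arg-type]


def global_distribution(traj: Trajectory) -> WindowDistribution:
    """Whole-series analogue of :func:`window_distribution` (diagnostic
    reference distribution)."""
    return window_distribution(traj, (0, traj.n_frames), index=-1)


def kantorovich(a: ECDF, b: ECDF) -> float:
    """Kantorovich / Wasserstein-1 distance between two 1-D distributions:
    the area between their CDFs, computed exactly on the union of
    breakpoints.  Equals the minimal earth-mover transport cost in 1-D."""
    grid = np.union1d(a.values, b.values)
    if grid.size < 2:
        return 0.0
    gaps = np.diff(grid)
    fa = a(grid[:-1])
    fb = b(grid[:-1])
    return float(np.sum(np.abs(fa - fb) * gaps))


def window_distance(u: WindowDistribution, v: WindowDistribution) -> float:
    """Sum of per-axis Kantorovich distances."""
    return sum(kantorovich(cu, cv) for cu, cv in zip(u.cdfs, v.cdfs))


def pairwise_distances(dists: list[WindowDistribution]) -> np.ndarray:
    """Symmetric zero-diagonal matrix of window distances."""
    m = len(dists)
    out = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            d = window_distance(dists[i], dists[j])
            out[i, j] = out[j, i] = d
    return out


def default_threshold(distances: np.ndarray) -> float:
    """Parameter-free clustering threshold: 0.75 times the median
    off-diagonal pairwise distance.  Always recorded in output; always
    overridable.  (Half the median leaves nearly every window a singleton on
    weakly ordered motion, which saturates downstream entropies.)"""
    m = distances.shape[0]
    if m < 2:
        return 0.0
    iu = np.triu_indices(m, k=1)
    return float(np.median(distances[iu]) * 0.75)


def cluster_windows(
    distances: np.ndarray,
    threshold: float,
    window_spec: WindowSpec | None = None,
    center_times: np.ndarray | None = None,
) -> StateAssignment:
    """Average-linkage agglomerative clustering of the windows, cut at
    ``threshold``; labels are renumbered so state 1 has the most windows,
    then descending by count, ties broken by first occurrence."""
    distances = np.asarray(distances, dtype=float)
    m = distances.shape[0]
    if distances.shape != (m, m):
        raise ValueError("distance matrix must be square")
    if not np.allclose(distances, distances.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(distances) != 0):
        raise ValueError("distance matrix must have zero diagonal")
    if np.any(distances < 0):
        raise ValueError("distances must be non-negative")

    if m == 1:
        raw = np.array([1])
    else:
        Z = linkage(squareform(distances, checks=False), method="average")
        raw = fcluster(Z, t=max(threshold, 0.0), criterion="distance")

    labels = _relabel_by_count(raw)
    spec = window_spec if window_spec is not None else WindowSpec(delta=2, hop=1)
    return StateAssignment(
        labels=labels,
        K=int(labels.max()),
        window_spec=spec,
        distances=distances,
        threshold=float(threshold),
        center_times=center_times,
    )


def _relabel_by_count(raw: np.ndarray) -> np.ndarray:
    raw = np.asarray(raw, dtype=int)
    uniq = np.unique(raw)
    counts = {u: int((raw == u).sum()) for u in uniq}
    first = {u: int(np.argmax(raw == u)) for u in uniq}
    order = sorted(uniq, key=lambda u: (-counts[u], first[u]))
    remap = {u: i + 1 for i, u in enumerate(order)}
    return np.array([remap[v] for v in raw], dtype=int)


def escape_times(assignment: StateAssignment) -> dict[int, list[tuple[int, bool]]]:
    """Dwell lengths per state from maximal runs of identical consecutive
    labels.  Each entry is ``(length_in_windows, censored)``; only the final
    run is censored (the exit was never observed)."""
    labels = assignment.labels
    out: dict[int, list[tuple[int, bool]]] = {k: [] for k in range(1, assignment.K + 1)}
    if len(labels) == 0:
        return out
    run_label = int(labels[0])
    run_len = 1
    for lab in labels[1:]:
        if lab == run_label:
            run_len += 1
        else:
            out[run_label].append((run_len, False))
            run_label = int(lab)
            run_len = 1
    out[run_label].append((run_len, True))
    return out


def extract_states(
    traj: Trajectory,
    spec: WindowSpec,
    threshold: float | None = None,
) -> tuple[StateAssignment, np.ndarray]:
    """Full window → distribution → distance → cluster pipeline.

    Returns the assignment and, as a diagnostic, each window's distance to
    the whole-series distribution (not used for clustering).
    """
    windows = segment(traj, spec)
    dists = [window_distribution(traj, w, index=i) for i, w in enumerate(windows)]
    D = pairwise_distances(dists)
    if threshold is None:
        threshold = default_threshold(D)
    center_times = np.array([d.center_time for d in dists])
    assignment = cluster_windows(D, threshold, window_spec=spec, center_times=center_times)
    ref = global_distribution(traj)
    to_global = np.array([window_distance(d, ref) for d in dists])
    return assignment, to_global
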