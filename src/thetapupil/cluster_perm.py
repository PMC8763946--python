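"""Cluster-based permutation test for paired sensor-level theta maps.

Tests a within-subject contrast (e.g. session S1 vs S4 theta power per
channel × time bin) with the nonparametric cluster statistic: bin-wise
dependent-samples t-values are thresholded at ``cluster_alpha``, thresholded
bins are grouped into clusters under spatial (channel-neighbourhood) ×
temporal (consecutive-bin) adjacency, each cluster is summarised by its
summed t, and the family-wise null distribution of the maximum |cluster sum|
is built by randomly flipping the sign of each subject's difference map
(the exchangeability move for a paired design).  The Monte-Carlo reference
distribution uses 500 draws by default; an exhaustive mode enumerates all
2^n sign patterns for small n and serves as the oracle for the Monte-Carlo
path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse, stats

from .montage import arc_distances

__all__ = ["NeighborGraph", "ClusterTestResult", "build_neighbors", "cluster_permutation_test"]


@dataclass
class NeighborGraph:
    """Symmetric channel adjacency with zero diagonal."""

    adjacency: np.ndarray  # (n_channels, n_channels) bool

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, bool)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        np.fill_diagonal(a, False)
        self.adjacency = a

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)


@dataclass
class ClusterTestResult:
    clusters: list[np.ndarray]  # each (k, 2) array of (channel, time) bins
    cluster_stats: np.ndarray  # summed t per cluster
    p_values: np.ndarray  # Monte-Carlo p per cluster
    sig_mask: np.ndarray  # (n_channels, n_times) bool at alpha
    t_obs: np.ndarray  # (n_channels, n_times)
    n_permutations: int


def build_neighbors(positions: np.ndarray, max_dist: float = 0.4) -> NeighborGraph:
    """Channels within ``max_dist`` radians of arc on the unit sphere.

    Channels left without any neighbour under the threshold are kept (with a
    warning); they can still form single-channel clusters.
    """
    import warnings

    pos = np.asarray(positions, float)
    if pos.shape[0] < 2:
        raise ValueError("need at least 2 channels")
    d = arc_distances(pos)
    adj = d <= max_dist
    np.fill_diagonal(adj, False)
    if (adj.sum(axis=1) == 0).any():
        warnings.warn("isolated channel(s) under the neighbour threshold", stacklevel=2)
    return NeighborGraph(adjacency=adj)


def _bin_adjacency(graph: NeighborGraph, n_times: int) -> sparse.csr_matrix:
    """Sparse adjacency over (channel, time) bins: spatial × temporal edges."""
    a_ch = sparse.csr_matrix(graph.adjacency.astype(np.int8))
    eye_t = sparse.identity(n_times, format="csr", dtype=np.int8)
    spatial = sparse.kron(a_ch, eye_t, format="csr")
    off = sparse.diags([1, 1], [1, -1], shape=(n_times, n_times), dtype=np.int8)
    temporal = sparse.kron(
        sparse.identity(graph.adjacency.shape[0], dtype=np.int8), off, format="csr"
    )
    return (spatial + temporal).tocsr()


def _cluster_sums(
    t_map: np.ndarray, thresh: float, adj: sparse.csr_matrix
) -> tuple[list[np.ndarray], np.ndarray]:
    """Signed clusters of suprathreshold bins and their summed t."""
    n_ch, n_t = t_map.shape
    flat = t_map.ravel()
    clusters: list[np.ndarray] = []
    sums: list[float] = []
    for sign in (1.0, -1.0):
        mask = sign * flat > thresh
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        sub = adj[idx][:, idx]
        n_comp, labels = sparse.csgraph.connected_components(sub, directed=False)
        for c in range(n_comp):
            members = idx[labels == c]
            clusters.append(np.column_stack(np.unravel_index(members, (n_ch, n_t))))
            sums.append(float(flat[members].sum()))
    return clusters, np.asarray(sums)


def _paired_t(diffs: np.ndarray) -> np.ndarray:
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    # zero-variance bins: 0/0 → 0, c/0 → huge-but-finite t
    return np.nan_to_num(t, posinf=1e12, neginf=-1e12)


def cluster_permutation_test(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    graph: NeighborGraph,
    n_perm: int = 500,
    alpha: float = 0.05,
    cluster_alpha: float = 0.05,
    seed: int | None = None,
    exhaustive: bool = False,
) -> ClusterTestResult:
    """Paired two-sided cluster permutation test on (subjects, channels, times).

    The cluster-forming threshold is the two-sided t critical value at
    ``cluster_alpha``; cluster p-values compare |summed t| against the
    permutation distribution of the maximum |cluster sum|.  ``seed`` is
    required for the Monte-Carlo path (identical seed ⇒ identical p).
    With ``exhaustive=True`` all 2^n sign flips are enumerated instead
    (n ≤ 20).
    """
    a = np.asarray(cond_a, float)
    b = np.asarray(cond_b, float)
    if a.shape != b.shape or a.ndim != 3:
        raise ValueError("conditions must be matching (subjects, channels, times) arrays")
    n_sub, n_ch, n_t = a.shape
    if n_sub < 2:
        raise ValueError("need at least 2 subjects")
    if n_ch != graph.adjacency.shape[0]:
        raise ValueError("graph size does not match channel count")
    diffs = a - b
    thresh = float(stats.t.ppf(1.0 - cluster_alpha / 2.0, n_sub - 1))
    adj = _bin_adjacency(graph, n_t)
    t_obs = _paired_t(diffs)
    clusters, sums = _cluster_sums(t_obs, thresh, adj)

    if exhaustive:
        if n_sub > 20:
            raise ValueError("exhaustive enumeration limited to 20 subjects")
        signs_iter = (
            np.array([1 if (p >> i) & 1 else -1 for i in range(n_sub)], float)
            for p in range(2**n_sub)
        )
        null = np.empty(2**n_sub)
        for j, signs in enumerate(signs_iter):
            t_p = _paired_t(diffs * signs[:, None, None])
            _, s_p = _cluster_sums(t_p, thresh, adj)
            null[j] = np.abs(s_p).max() if s_p.size else 0.0
        # observed pattern is one of the enumerated ones: plain fraction
        p_vals = np.array([(null >= abs(s) - 1e-12).mean() for s in sums])
        n_eff = null.size
    else:
        if seed is None:
            raise ValueError("Monte-Carlo permutation requires a seed")
        rng = np.random.default_rng(seed)
        null = np.empty(n_perm)
        for j in range(n_perm):
            signs = rng.choice([-1.0, 1.0], size=n_sub)
            t_p = _paired_t(diffs * signs[:, None, None])
            _, s_p = _cluster_sums(t_p, thresh, adj)
            null[j] = np.abs(s_p).max() if s_p.size else 0.0
        p_vals = np.array(
            [(1 + (null >= abs(s) - 1e-12).sum()) / (n_perm + 1) for s in sums]
        )
        n_eff = n_perm

    sig_mask = np.zeros((n_ch, n_t), bool)
    for cl, p in zip(clusters, p_vals):
        if p <= alpha:
            sig_mask[cl[:, 0], cl[:, 1]] = True
    return ClusterTestResult(
        clusters=clusters,
        cluster_stats=sums,
        p_values=p_vals,
        sig_mask=sig_mask,
        t_obs=t_obs,
        n_permutations=n_eff,
    )
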