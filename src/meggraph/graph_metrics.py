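"""Weighted clustering, harmonic-mean path length, and surrogate normalization.

Edge weights are connection strengths (PLI values), so path costs are
inverse weights: strong connections are short. The average path length uses
the harmonic mean so that disconnected pairs contribute zero rather than
infinity. Raw C_w and L_w depend on network size and the weight
distribution; both are therefore normalized by their means over surrogate
networks obtained by shuffling the edge weights over the fixed vertex set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import dijkstra

__all__ = [
    "WeightedGraph",
    "NormalizedMetrics",
    "weighted_clustering",
    "weighted_path_length",
    "surrogate_graph",
    "normalize_metrics",
]


@dataclass
class WeightedGraph:
    """Undirected weighted graph as a symmetric nonnegative matrix, zero diagonal."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"weights must be square, got shape {w.shape}")
        if not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        w = 0.5 * (w + w.T)  # remove numerical asymmetry
        np.fill_diagonal(w, 0.0)
        self.weights = w

    @property
    def n_vertices(self) -> int:
        return self.weights.shape[0]

    @property
    def strengths(self) -> np.ndarray:
        return self.weights.sum(axis=1)


def _as_weights(g: "WeightedGraph | np.ndarray") -> np.ndarray:
    if isinstance(g, WeightedGraph):
        return g.weights
    return WeightedGraph(np.asarray(g)).weights


def weighted_clustering(g: "WeightedGraph | np.ndarray") -> tuple[np.ndarray, float]:
    """Per-vertex weighted clustering coefficients and their mean C_w.

    C_w,i = sum_{k != l} w_ik w_il w_kl / sum_{k != l} w_ik w_il; the ratio is
    identical over ordered and unordered neighbour pairs. Vertices with fewer
    than two positive-weight neighbours have no triples and get C_w,i = 0.
    """
    w = _as_weights(g)
    n = w.shape[0]
    if n < 3:
        raise ValueError("clustering requires at least 3 vertices")
    num = np.einsum("ik,kl,li->i", w, w, w)  # closed triples through i
    s = w.sum(axis=1)
    den = s**2 - (w**2).sum(axis=1)  # open triples at i
    cw = np.zeros(n)
    ok = (den > 0) & ((w > 0).sum(axis=1) >= 2)
    cw[ok] = num[ok] / den[ok]
    return cw, float(cw.mean())


def weighted_path_length(g: "WeightedGraph | np.ndarray") -> tuple[np.ndarray, float]:
    """Pairwise shortest-path lengths and their harmonic mean L_w.

    Traversing an edge of weight w costs 1/w (zero-weight edges are absent);
    L_ij is the minimal total cost. L_w = N(N-1) / sum_{i!=j} 1/L_ij, with
    disconnected pairs contributing 1/L_ij = 0. A graph with no finite pair
    distances has undefined L_w, reported as inf.
    """
    w = _as_weights(g)
    n = w.shape[0]
    if n < 2:
        raise ValueError("path length requires at least 2 vertices")
    with np.errstate(divide="ignore"):
        cost = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
    dist = dijkstra(cost, directed=False)
    off = ~np.eye(n, dtype=bool)
    inv = np.zeros_like(dist)
    finite = np.isfinite(dist) & (dist > 0) & off
    inv[finite] = 1.0 / dist[finite]
    denom = inv[off].sum()
    lw = np.inf if denom == 0 else n * (n - 1) / denom
    return dist, float(lw)


def surrogate_graph(g: "WeightedGraph | np.ndarray", seed) -> WeightedGraph:
    """Surrogate network: edge weights randomly shuffled over the network.

    The upper-triangle weights are permuted uniformly at random and
    re-symmetrized, preserving the weight multiset exactly.
    """
    w = _as_weights(g)
    n = w.shape[0]
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, k=1)
    vals = rng.permutation(w[iu])
    out = np.zeros_like(w)
    out[iu] = vals
    out = out + out.T
    return WeightedGraph(out)


@dataclass
class NormalizedMetrics:
    """C_w and L_w together with surrogate references and normalized ratios."""

    Cw: float
    Lw: float
    Cws: float
    Lws: float
    Cw_ratio: float
    Lw_ratio: float
    n_surrogates: int
    seed: int | None


def normalize_metrics(
    g: "WeightedGraph | np.ndarray", n_surrogates: int = 1000, seed=None
) -> NormalizedMetrics:
    """Normalize C_w and L_w by their means over weight-shuffled surrogates.

    The default of 1000 surrogates matches full-scale analyses; tests use
    fewer. One master seed spawns an independent substream per surrogate so
    results are reproducible and insensitive to evaluation order.
    """
    if n_surrogates < 1:
        raise ValueError("n_surrogates must be >= 1")
    w = _as_weights(g)
    _, cw = weighted_clustering(w)
    _, lw = weighted_path_length(w)
    streams = np.random.SeedSequence(seed).spawn(n_surrogates)
    cs = np.empty(n_surrogates)
    ls = np.empty(n_surrogates)
    for k, ss in enumerate(streams):
        sur = surrogate_graph(w, ss)
        _, cs[k] = weighted_clustering(sur)
        _, ls[k] = weighted_path_length(sur)
    cws = float(cs.mean())
    lws = float(ls.mean())  # harmonic rule keeps disconnected surrogates finite
    return NormalizedMetrics(
        Cw=cw,
        Lw=lw,
        Cws=cws,
        Lws=lws,
        Cw_ratio=cw / cws if cws > 0 else np.nan,
        Lw_ratio=lw / lws if lws > 0 else np.nan,
        n_surrogates=n_surrogates,
        seed=seed if isinstance(seed, int) else None,
    )
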