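"""Weighted modularity, simulated-annealing partition search, and node roles.

Modularity of a partition of a weighted graph:

    Q = sum_s [ W_s / W_total - (d_s / (2 W_total))^2 ]

where W_s is the total weight inside module s, d_s the summed strength of
its vertices, and W_total the total edge weight. Q = 0 for the trivial
single-module partition. The optimal partition is searched by simulated
annealing on the cost C = -Q with a geometric cooling schedule; node roles
within the resulting modules are quantified by the within-module degree
z-score and the participation coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph_metrics import WeightedGraph, _as_weights

__all__ = [
    "Partition",
    "AnnealingSchedule",
    "NodeRoles",
    "modularity",
    "anneal_partition",
    "within_module_z",
    "participation",
]


@dataclass
class Partition:
    """Assignment of each vertex to a module, with the partition's modularity."""

    labels: np.ndarray
    Q: float = np.nan

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ValueError("labels must be a 1-D vertex -> module vector")

    @property
    def n_modules(self) -> int:
        return len(np.unique(self.labels))


@dataclass
class AnnealingSchedule:
    """Geometric cooling schedule for the modularity search.

    Full-scale default: start at T = 1, multiply by 0.995 every 100 steps,
    for 10^6 proposal steps in total.
    """

    t0: float = 1.0
    cooling: float = 0.995
    steps_per_cooling: int = 100
    total_steps: int = 1_000_000
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.cooling < 1:
            raise ValueError("cooling factor must lie in (0, 1)")
        if self.total_steps < 1 or self.steps_per_cooling < 1:
            raise ValueError("step counts must be positive")


def _check_partition(w: np.ndarray, labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if labels.shape != (w.shape[0],):
        raise ValueError("partition must label every vertex exactly once")
    return labels


def modularity(g: "WeightedGraph | np.ndarray", p: "Partition | np.ndarray") -> float:
    """Modularity Q of a partition of a weighted graph."""
    w = _as_weights(g)
    if w.shape[0] == 0:
        raise ValueError("modularity of an empty graph is undefined")
    labels = _check_partition(w, p.labels if isinstance(p, Partition) else p)
    w_total = w.sum() / 2.0
    if w_total <= 0:
        raise ValueError("modularity requires positive total edge weight")
    strengths = w.sum(axis=1)
    q = 0.0
    for m in np.unique(labels):
        mask = labels == m
        ws = w[np.ix_(mask, mask)].sum() / 2.0
        ds = strengths[mask].sum()
        q += ws / w_total - (ds / (2.0 * w_total)) ** 2
    return float(q)


def anneal_partition(
    g: "WeightedGraph | np.ndarray", sched: AnnealingSchedule | None = None
) -> Partition:
    """Search for the maximum-modularity partition by simulated annealing.

    Each vertex starts in its own module. A step reassigns one random vertex
    to a random module label in [0, N); the move is accepted when the cost
    C = -Q does not increase, otherwise with Metropolis probability
    exp(-dC / T). The best (highest-Q) partition encountered anywhere along
    the walk is returned, guarding against late-schedule drift; the trivial
    single-module partition (Q = 0) serves as a floor, so the result is
    never worse than no modular structure at all.
    """
    w = _as_weights(g)
    n = w.shape[0]
    if n < 2:
        raise ValueError("annealing requires at least 2 vertices")
    if sched is None:
        sched = AnnealingSchedule()
    w_total = w.sum() / 2.0
    if w_total <= 0:
        raise ValueError("annealing requires positive total edge weight")

    rng = np.random.default_rng(sched.seed)
    strengths = w.sum(axis=1)
    labels = np.arange(n)

    # running per-module strength totals d_s; module ids live in [0, n)
    degsum = strengths.copy().astype(float)  # singleton start

    q = modularity(w, labels)
    best_q, best_labels = q, labels.copy()
    temp = sched.t0
    two_wt = 2.0 * w_total

    chunk = 8192
    done = 0
    while done < sched.total_steps:
        k = min(chunk, sched.total_steps - done)
        verts = rng.integers(0, n, size=k)
        props = rng.integers(0, n, size=k)
        unifs = rng.random(size=k)
        for t in range(k):
            step = done + t
            if step and step % sched.steps_per_cooling == 0:
                temp *= sched.cooling
            v = verts[t]
            b = props[t]
            a = labels[v]
            if a == b:
                continue
            row = w[v]
            k_va = row @ (labels == a)
            k_vb = row @ (labels == b)
            sv = strengths[v]
            dq = (k_vb - k_va) / w_total
            dq -= ((degsum[b] + sv) / two_wt) ** 2 - (degsum[b] / two_wt) ** 2
            dq -= ((degsum[a] - sv) / two_wt) ** 2 - (degsum[a] / two_wt) ** 2
            if dq >= 0 or unifs[t] < np.exp(dq / temp):
                labels[v] = b
                degsum[a] -= sv
                degsum[b] += sv
                q += dq
                if q > best_q:
                    best_q = q
                    best_labels = labels.copy()
        done += k

    if best_q < 0:
        best_labels = np.zeros(n, dtype=int)  # single-module floor, Q = 0
    # compact labels to 0..m-1 and recompute Q exactly (drift-free)
    _, compact = np.unique(best_labels, return_inverse=True)
    return Partition(labels=compact, Q=modularity(w, compact))


@dataclass
class NodeRoles:
    """Per-vertex module roles: within-module degree z and participation."""

    Z: np.ndarray
    P: np.ndarray
    Pw: float = field(init=False)
    Zbar: float = field(init=False)

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        self.Pw = float(self.P.mean())
        self.Zbar = float(self.Z.mean())


def within_module_z(
    g: "WeightedGraph | np.ndarray", p: "Partition | np.ndarray"
) -> np.ndarray:
    """Within-module degree z-score per vertex.

    kappa_i is the summed weight from vertex i to other vertices in its own
    module; Z_i standardizes kappa_i against its module's distribution using
    the population standard deviation. Singleton modules and modules with
    zero spread get Z = 0.
    """
    w = _as_weights(g)
    labels = _check_partition(w, p.labels if isinstance(p, Partition) else p)
    z = np.zeros(w.shape[0])
    for m in np.unique(labels):
        mask = labels == m
        if mask.sum() < 2:
            continue
        kappa = w[np.ix_(mask, mask)].sum(axis=1)
        sd = kappa.std()  # population std
        if sd > 0:
            z[mask] = (kappa - kappa.mean()) / sd
    return z


def participation(
    g: "WeightedGraph | np.ndarray", p: "Partition | np.ndarray"
) -> NodeRoles:
    """Participation coefficient per vertex and network mean P_w.

    P_i = 1 - sum_m (kappa_im / s_i)^2 over modules m, where kappa_im is the
    weight from i into module m and s_i the total strength of i. P_i = 0 for
    a vertex whose weight is confined to one module, and for isolated
    vertices (s_i = 0) by convention.
    """
    w = _as_weights(g)
    labels = _check_partition(w, p.labels if isinstance(p, Partition) else p)
    mods, inverse = np.unique(labels, return_inverse=True)
    onehot = np.zeros((w.shape[0], len(mods)))
    onehot[np.arange(w.shape[0]), inverse] = 1.0
    kappa = w @ onehot  # N x M
    s = w.sum(axis=1)
    part = np.zeros(w.shape[0])
    ok = s > 0
    part[ok] = 1.0 - ((kappa[ok] / s[ok, None]) ** 2).sum(axis=1)
    return NodeRoles(Z=within_module_z(w, labels), P=np.clip(part, 0.0, 1.0))
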