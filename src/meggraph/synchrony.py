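"""Laplacian eigenratio synchronizability of a weighted graph.

The graph Laplacian L = D - W (D the diagonal matrix of weighted vertex
strengths) of a symmetric nonnegative graph has a real spectrum
0 = lambda_1 <= lambda_2 <= ... <= lambda_N. The stability of the fully
synchronous state of identical oscillators coupled through the graph is
governed by the eigenratio R = lambda_N / lambda_2; we report its inverse
S = lambda_2 / lambda_N, which lies in [0, 1] and is larger for networks
with a more stable synchronous state. A disconnected graph has
lambda_2 = 0 and hence S = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigvalsh

from .graph_metrics import WeightedGraph, _as_weights

__all__ = ["SpectrumResult", "laplacian", "synchronizability"]

#: eigenvalues below ZERO_TOL * lambda_N are treated as exactly zero
ZERO_TOL = 1e-9


@dataclass
class SpectrumResult:
    """Laplacian spectrum with the eigenratio and synchronizability."""

    eigenvalues: np.ndarray
    lambda2: float
    lambdaN: float
    R: float
    S: float
    degenerate: bool = False  # all-zero graph: S reported as 0 by convention


def laplacian(g: "WeightedGraph | np.ndarray") -> np.ndarray:
    """Weighted graph Laplacian: diagonal of strengths minus the weight matrix."""
    w = _as_weights(g)
    return np.diag(w.sum(axis=1)) - w


def synchronizability(g: "WeightedGraph | np.ndarray") -> SpectrumResult:
    """Laplacian spectrum and synchronizability S = lambda_2 / lambda_N."""
    w = _as_weights(g)  # rejects asymmetric input
    if w.shape[0] < 2:
        raise ValueError("synchronizability requires at least 2 vertices")
    evals = np.sort(eigvalsh(laplacian(w)))
    lam_n = float(evals[-1])
    if lam_n <= 0:
        return SpectrumResult(
            eigenvalues=np.zeros_like(evals),
            lambda2=0.0,
            lambdaN=0.0,
            R=np.inf,
            S=0.0,
            degenerate=True,
        )
    evals[np.abs(evals) < ZERO_TOL * lam_n] = 0.0
    lam2 = float(max(evals[1], 0.0))
    s = lam2 / lam_n
    return SpectrumResult(
        eigenvalues=evals,
        lambda2=lam2,
        lambdaN=lam_n,
        R=np.inf if lam2 == 0 else lam_n / lam2,
        S=float(np.clip(s, 0.0, 1.0)),
    )
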