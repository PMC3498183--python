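"""Phase lag index (PLI) functional connectivity.

The PLI between two signals is the absolute mean of the sign of their
wrapped instantaneous phase differences:

    PLI = | < sign(dPhi(t_k)) > |,   dPhi wrapped to (-pi, pi]

It is 0 when the phase-difference distribution is symmetric around zero
(no consistent leader) and 1 when one signal always leads or always lags.
Because an instantaneously mixed common source produces phase differences
of exactly 0 or pi, which carry no asymmetry, the PLI is insensitive to
volume conduction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .preprocessing import EDGE_TRIM_FRACTION, EpochedRecording

__all__ = [
    "ConnectivityMatrix",
    "instantaneous_phase",
    "pli_pair",
    "pli_matrix",
    "overall_pli",
]


@dataclass
class ConnectivityMatrix:
    """Symmetric channels x channels PLI matrix for one subject and band."""

    weights: np.ndarray
    band: str = ""
    subject_id: str = ""
    n_epochs_used: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"weights must be square, got shape {w.shape}")
        if not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be zero")
        if w.min() < 0 or w.max() > 1:
            raise ValueError("PLI weights must lie in [0, 1]")
        self.weights = w

    @property
    def n_channels(self) -> int:
        return self.weights.shape[0]


def instantaneous_phase(x: np.ndarray) -> np.ndarray:
    """Instantaneous phase of a real signal via the analytic signal, in (-pi, pi]."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 4:
        raise ValueError("signal must be a 1-D vector of length >= 4")
    if np.ptp(x) == 0:
        raise ValueError("phase is undefined for a constant signal")
    return np.angle(hilbert(x))


def _wrap_phase(dphi: np.ndarray) -> np.ndarray:
    # angle(exp(i*x)) maps onto (-pi, pi]; the boundary pi keeps sign +1.
    return np.angle(np.exp(1j * np.asarray(dphi, dtype=float)))


#: wrapped differences below this magnitude count as exactly zero lag;
#: absorbs float rounding in the complex products (identical signals must
#: yield sign 0, not noise-driven random signs)
_ZERO_LAG_TOL = 1e-12


def _lag_signs(wrapped: np.ndarray) -> np.ndarray:
    s = np.sign(wrapped)
    s[np.abs(wrapped) < _ZERO_LAG_TOL] = 0.0
    return s


def pli_pair(phase_diff: np.ndarray) -> float:
    """PLI of a phase-difference time series.

    The series is wrapped to (-pi, pi] first; samples with a wrapped
    difference of exactly 0 contribute sign 0 (neither leading nor lagging).
    """
    phase_diff = np.asarray(phase_diff, dtype=float)
    if phase_diff.size == 0:
        raise ValueError("phase_diff must be nonempty")
    return float(np.abs(np.mean(_lag_signs(_wrap_phase(phase_diff)))))


def pli_matrix(rec: EpochedRecording, edge_trim: float = EDGE_TRIM_FRACTION) -> ConnectivityMatrix:
    """Pairwise PLI between all channels, averaged over epochs.

    Per epoch, instantaneous phases are extracted channel-wise, a fraction
    ``edge_trim`` of samples is dropped at both epoch edges, and the PLI is
    evaluated for every channel pair; epochs are treated as independent
    selections, so per-epoch matrices are averaged.
    """
    if rec.n_channels < 2:
        raise ValueError("need at least 2 channels for connectivity")
    if rec.n_epochs < 1:
        raise ValueError("need at least 1 epoch")
    if not 0 <= edge_trim < 0.5:
        raise ValueError("edge_trim must lie in [0, 0.5)")

    n = rec.n_channels
    trim = int(round(edge_trim * rec.n_samples))
    acc = np.zeros((n, n))
    for e in range(rec.n_epochs):
        phases = np.angle(hilbert(rec.data[:, :, e], axis=1))
        if trim:
            phases = phases[:, trim:-trim]
        z = np.exp(1j * phases)
        for i in range(n - 1):
            # wrapped phase difference phi_i - phi_j for all j > i
            dphi = np.angle(z[i] * np.conj(z[i + 1 :]))
            acc[i, i + 1 :] += np.abs(np.mean(_lag_signs(dphi), axis=1))
    acc /= rec.n_epochs
    acc = acc + acc.T
    return ConnectivityMatrix(
        weights=acc,
        band=rec.band or "",
        subject_id=rec.subject_id,
        n_epochs_used=rec.n_epochs,
    )


def overall_pli(cm: ConnectivityMatrix) -> float:
    """Mean PLI over all channel pairs (off-diagonal upper triangle)."""
    w = cm.weights
    iu = np.triu_indices(w.shape[0], k=1)
    return float(w[iu].mean())
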