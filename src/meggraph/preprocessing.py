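"""Epoch handling and band-pass filtering into canonical MEG frequency bands.

Resting-state MEG is analysed per artifact-free epoch, per frequency band.
Filtering is zero-phase (forward-backward IIR) because any phase distortion
introduced here would bias the downstream phase-lag estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

__all__ = [
    "BandDefinition",
    "EpochedRecording",
    "EpochRejectionError",
    "standard_bands",
    "epoch_duration_seconds",
    "bandpass",
    "validate_epochs",
    "EDGE_TRIM_FRACTION",
]

#: Fraction of samples discarded at each epoch edge during phase analysis,
#: guarding against filter and analytic-signal transients.
EDGE_TRIM_FRACTION = 0.05


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band with half-open physical limits in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0.0 < self.low < self.high):
            raise ValueError(
                f"band {self.name!r}: need 0 < low < high, got ({self.low}, {self.high})"
            )

    def validate_for_rate(self, sampling_rate: float) -> None:
        if self.high >= sampling_rate / 2.0:
            raise ValueError(
                f"band {self.name!r} upper edge {self.high} Hz is at or above "
                f"the Nyquist frequency {sampling_rate / 2.0} Hz"
            )


# Canonical seven-band decomposition of resting-state MEG; note the gap at
# 45-55 Hz avoiding the 50 Hz mains frequency.
_STANDARD_BANDS = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("lower_alpha", 8.0, 10.0),
    BandDefinition("upper_alpha", 10.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("lower_gamma", 30.0, 45.0),
    BandDefinition("higher_gamma", 55.0, 80.0),
)


def standard_bands() -> list[BandDefinition]:
    """Return the seven standard analysis bands, delta through higher gamma."""
    return list(_STANDARD_BANDS)


def band_by_name(name: str) -> BandDefinition:
    for band in _STANDARD_BANDS:
        if band.name == name:
            return band
    known = ", ".join(b.name for b in _STANDARD_BANDS)
    raise KeyError(f"unknown band {name!r}; known bands: {known}")


def epoch_duration_seconds(n_samples: int, sampling_rate: float) -> float:
    """Duration of an epoch of ``n_samples`` at ``sampling_rate`` Hz, in seconds."""
    if n_samples <= 0 or sampling_rate <= 0:
        raise ValueError("n_samples and sampling_rate must be positive")
    return n_samples / sampling_rate


class EpochRejectionError(RuntimeError):
    """Raised when a subject retains fewer valid epochs than required."""


@dataclass
class EpochedRecording:
    """One subject's multichannel recording, organised channels x samples x epochs."""

    data: np.ndarray
    sampling_rate: float
    channel_ids: list[str] = field(default_factory=list)
    subject_id: str = ""
    band: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be 3-D (channels, samples, epochs), got shape {self.data.shape}"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"recording {self.subject_id!r} contains non-finite samples")
        if not self.channel_ids:
            self.channel_ids = [f"ch{i:03d}" for i in range(self.data.shape[0])]
        if len(self.channel_ids) != self.data.shape[0]:
            raise ValueError("channel_ids length must match the channel dimension")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_epochs(self) -> int:
        return self.data.shape[2]

    @property
    def duration_seconds(self) -> float:
        return epoch_duration_seconds(self.n_samples, self.sampling_rate)


def bandpass(rec: EpochedRecording, band: BandDefinition, order: int = 4) -> EpochedRecording:
    """Zero-phase band-pass filter every channel of every epoch.

    A Butterworth filter of the given order is applied forward and backward
    (``sosfiltfilt``), doubling the effective order and cancelling the phase
    response exactly. Output shape equals input shape.
    """
    band.validate_for_rate(rec.sampling_rate)
    sos = signal.butter(
        order, [band.low, band.high], btype="bandpass", fs=rec.sampling_rate, output="sos"
    )
    filtered = signal.sosfiltfilt(sos, rec.data, axis=1)
    return replace(rec, data=filtered, band=band.name)


def validate_epochs(
    rec: EpochedRecording, max_abs: float, min_epochs: int = 1
) -> EpochedRecording:
    """Drop epochs whose peak absolute amplitude exceeds ``max_abs``.

    Deterministic stand-in for visual artifact rejection: an epoch with any
    sample beyond the threshold is discarded wholesale. Raises
    :class:`EpochRejectionError` naming the subject when fewer than
    ``min_epochs`` survive.
    """
    if max_abs <= 0:
        raise ValueError("max_abs must be positive")
    peaks = np.max(np.abs(rec.data), axis=(0, 1))
    keep = peaks <= max_abs
    if keep.sum() < min_epochs:
        raise EpochRejectionError(
            f"subject {rec.subject_id!r}: only {int(keep.sum())} of {rec.n_epochs} "
            f"epochs pass the {max_abs:g} amplitude threshold (need {min_epochs})"
        )
    return replace(rec, data=rec.data[:, :, keep])
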