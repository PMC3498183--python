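"""Synthetic resting-state cohorts from lag-coupled phase oscillators.

Stands in for raw multichannel MEG. Each channel is a phase oscillator with
a natural frequency drawn inside the analysis band; oscillators in the same
planted module are coupled more strongly than oscillators in different
modules, and every coupling acts through a fixed transmission lag so that
coupled pairs lock at a *nonzero* phase difference — the only feature the
phase lag index can detect. The observed signal is the cosine of the phase,
spread instantaneously across channels by a nonnegative unit-diagonal
mixing matrix (emulating volume conduction) plus white sensor noise.

A cohort adds the clinical layer: groups with multiplicative effects on the
coupling parameters, per-subject parameter jitter, and clinical covariates
(seizure frequency per month, epilepsy duration, cognitive z-scores) tied
to each subject's realized ground-truth network metric through monotone
links with additive noise, so that rank correlations are planted by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .modularity import modularity
from .preprocessing import EpochedRecording
from .synchrony import synchronizability

__all__ = [
    "OscillatorModel",
    "CovariateLink",
    "CohortSpec",
    "SubjectRecord",
    "generate_epoch",
    "generate_recording",
    "generate_cohort",
    "iter_cohort",
]

COGNITIVE_DOMAINS = ("attention", "executive", "memory")

#: Half-saturation coupling (rad/s) of the planted coupling -> edge-weight
#: transform w = k / (k + PLI_SATURATION) used for ground-truth metrics.
#: The measured PLI saturates with coupling strength in the same way, so
#: ground-truth metrics and measured metrics share their monotone drivers.
PLI_SATURATION = 20.0


@dataclass
class OscillatorModel:
    """Generative parameters for one subject's multichannel recording.

    Couplings are in rad/s; ``phase_lag`` is the locked phase offset (rad)
    planted between coupled oscillators; ``mixing_strength`` in [0, 1] sets
    the instantaneous cross-channel spread; ``noise_sd`` is white sensor
    noise in signal units (the source signal has unit amplitude).
    """

    n_channels: int
    sampling_rate: float = 625.0
    band: tuple[float, float] = (4.0, 8.0)
    module_assignment: np.ndarray | None = None
    within_coupling: float = 40.0
    between_coupling: float = 8.0
    phase_lag: float = 0.6
    noise_sd: float = 1.0
    mixing_strength: float = 0.1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        low, high = self.band
        if not (0.0 < low < high < self.sampling_rate / 2.0):
            raise ValueError(
                f"band {self.band} must lie inside (0, {self.sampling_rate / 2}) Hz"
            )
        if self.within_coupling < 0 or self.between_coupling < 0:
            raise ValueError("couplings must be nonnegative")
        if not 0.0 <= self.mixing_strength <= 1.0:
            raise ValueError("mixing_strength must lie in [0, 1]")
        if self.module_assignment is None:
            self.module_assignment = np.zeros(self.n_channels, dtype=int)
        self.module_assignment = np.asarray(self.module_assignment, dtype=int)
        if self.module_assignment.shape != (self.n_channels,):
            raise ValueError("module_assignment must label every channel exactly once")

    def coupling_matrix(self) -> np.ndarray:
        """Planted coupling-strength matrix (rad/s), zero diagonal."""
        same = self.module_assignment[:, None] == self.module_assignment[None, :]
        k = np.where(same, self.within_coupling, self.between_coupling).astype(float)
        np.fill_diagonal(k, 0.0)
        return k


def generate_epoch(
    model: OscillatorModel, n_samples: int, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Simulate one epoch; returns a channels x samples array.

    Euler integration at the sampling interval of

        dtheta_i/dt = 2 pi f_i + (1/N) sum_j K_ij sin(theta_j - theta_i + A_ij)

    with natural frequencies f_i uniform in the band and the antisymmetric
    lag matrix A_ij = +-phase_lag (sign of j - i). The antisymmetry matters:
    a symmetric lag cancels out of the pairwise phase-difference dynamics,
    whereas the antisymmetric lag makes coupled pairs lock near a nonzero
    phase difference. Observation: cos(theta), mixed instantaneously with
    unit diagonal, plus white noise.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    low, high = model.band
    if not (0.0 < low < high < model.sampling_rate / 2.0):
        raise ValueError("band must lie inside (0, Nyquist)")
    if rng is None:
        rng = np.random.default_rng(model.seed)

    n = model.n_channels
    dt = 1.0 / model.sampling_rate
    freqs = rng.uniform(low, high, size=n)
    theta = rng.uniform(-np.pi, np.pi, size=n)

    idx = np.arange(n)
    lag_sign = np.sign(idx[None, :] - idx[:, None])  # antisymmetric
    k_eff = (model.coupling_matrix() / n) * np.exp(1j * model.phase_lag * lag_sign)

    omega = 2.0 * np.pi * freqs
    x = np.empty((n, n_samples))
    for t in range(n_samples):
        x[:, t] = np.cos(theta)
        z = np.exp(1j * theta)
        drive = (k_eff @ z) * np.conj(z)
        theta = theta + dt * (omega + drive.imag)

    mu = model.mixing_strength
    if mu > 0 and n > 1:
        spread = (x.sum(axis=0, keepdims=True) - x) / (n - 1)
        x = x + mu * spread
    if model.noise_sd > 0:
        x = x + rng.normal(0.0, model.noise_sd, size=x.shape)
    return x


def generate_recording(
    model: OscillatorModel,
    n_epochs: int,
    n_samples: int,
    subject_id: str = "sim",
    rng: np.random.Generator | None = None,
) -> EpochedRecording:
    """Simulate ``n_epochs`` independent epochs as one EpochedRecording."""
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1")
    if rng is None:
        rng = np.random.default_rng(model.seed)
    data = np.stack(
        [generate_epoch(model, n_samples, rng=rng) for _ in range(n_epochs)], axis=2
    )
    return EpochedRecording(
        data=data, sampling_rate=model.sampling_rate, subject_id=subject_id
    )


@dataclass(frozen=True)
class CovariateLink:
    """Monotone link from a ground-truth network metric to a covariate.

    The metric is z-scored within each group; ``seizure_freq`` uses a
    log-linear link (always positive, strictly monotone), cognition domains
    a linear one. ``noise_sd`` is the SD of the additive noise on the linear
    predictor; 0 makes the link deterministic and the within-group rank
    correlation exactly +-1.
    """

    metric: str = "S"
    target: str = "seizure_freq"  # or "cognition"
    slope: float = -1.0
    noise_sd: float = 1.2


@dataclass
class SubjectRecord:
    """Clinical metadata plus planted ground truth for one synthetic subject."""

    subject_id: str
    group: str
    seizure_freq: float
    epilepsy_duration: float
    cognition: dict[str, float]
    cognition_avg: float
    ground_truth: dict[str, float]
    model: OscillatorModel | None = None


@dataclass
class CohortSpec:
    """Ground-truth description of a synthetic cohort.

    Defaults mirror the full-scale study structure: four groups of
    13/12/10/36 subjects, 136 channels at 625 Hz, five epochs of 4096
    samples, theta-band coupling. Group effects push the LGG-like and
    NGL-like groups toward stronger modular contrast (higher within-module,
    lower between-module coupling), the direction that lowers
    synchronizability and raises normalized clustering.
    """

    groups: tuple[tuple[str, int], ...] = (
        ("LGG", 13),
        ("HGG", 12),
        ("NGL", 10),
        ("CTL", 36),
    )
    n_channels: int = 136
    sampling_rate: float = 625.0
    band: tuple[float, float] = (4.0, 8.0)
    n_modules: int = 5
    within_coupling: float = 40.0
    between_coupling: float = 8.0
    phase_lag: float = 0.6
    noise_sd: float = 1.0
    mixing_strength: float = 0.1
    subject_sigma: float = 0.2  # lognormal SD of per-subject coupling-level jitter
    effect_map: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            # stronger modular contrast and a slightly lower coupling level:
            # lowers synchronizability, raises normalized clustering
            "LGG": {"within_coupling": 1.05, "between_coupling": 0.6},
            "NGL": {"within_coupling": 1.03, "between_coupling": 0.7},
        }
    )
    covariate_links: tuple[CovariateLink, ...] = (
        CovariateLink(metric="S", target="seizure_freq", slope=-1.0, noise_sd=1.2),
        CovariateLink(metric="S", target="cognition", slope=1.0, noise_sd=0.75),
    )
    control_group: str = "CTL"
    n_epochs: int = 5
    epoch_samples: int = 4096
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("cohort needs at least one group")
        if any(n < 1 for _, n in self.groups):
            raise ValueError("every group needs at least one subject")
        if self.n_modules < 1 or self.n_modules > self.n_channels:
            raise ValueError("n_modules must lie in [1, n_channels]")
        if self.n_epochs < 1 or self.epoch_samples < 2:
            raise ValueError("need n_epochs >= 1 and epoch_samples >= 2")

    @property
    def n_subjects(self) -> int:
        return sum(n for _, n in self.groups)

    def module_assignment(self) -> np.ndarray:
        """Channels assigned to modules in contiguous, near-equal blocks."""
        return np.sort(np.arange(self.n_channels) % self.n_modules)


# per-group clinical baselines (log-median seizures/month, median epilepsy
# duration in months, cognitive domain z intercepts); groups absent here are
# treated as seizure-free controls with missing clinical covariates
_CLINICAL_BASELINES = {
    "LGG": {"log_seizure": np.log(5.0), "duration_median": 44.0,
            "cognition": {"attention": -1.1, "executive": -1.2, "memory": 0.0}},
    "HGG": {"log_seizure": np.log(8.0), "duration_median": 20.0,
            "cognition": {"attention": -0.5, "executive": -1.0, "memory": 0.0}},
    "NGL": {"log_seizure": np.log(20.0), "duration_median": 228.0,
            "cognition": {"attention": -1.1, "executive": -1.2, "memory": 0.0}},
}


def _subject_model(spec: CohortSpec, group: str, jitter: float, seed: int) -> OscillatorModel:
    mult = spec.effect_map.get(group, {})
    return OscillatorModel(
        n_channels=spec.n_channels,
        sampling_rate=spec.sampling_rate,
        band=spec.band,
        module_assignment=spec.module_assignment(),
        within_coupling=spec.within_coupling * mult.get("within_coupling", 1.0) * jitter,
        between_coupling=spec.between_coupling * mult.get("between_coupling", 1.0) * jitter,
        phase_lag=spec.phase_lag * mult.get("phase_lag", 1.0),
        noise_sd=spec.noise_sd * mult.get("noise_sd", 1.0),
        mixing_strength=min(spec.mixing_strength * mult.get("mixing_strength", 1.0), 1.0),
        seed=seed,
    )


def _ground_truth_metrics(model: OscillatorModel) -> dict[str, float]:
    """Network metrics of the planted (noise-free) coupling graph.

    Couplings (rad/s) map to edge weights through the saturating transform
    w = k / (k + PLI_SATURATION), emulating how the measured PLI saturates
    with coupling strength; a uniformly stronger-coupled subject therefore
    has a more homogeneous planted graph and higher planted S, matching the
    direction of the measurement.
    """
    k = model.coupling_matrix()
    w = k / (k + PLI_SATURATION)
    np.fill_diagonal(w, 0.0)
    gt = {
        "within_coupling": model.within_coupling,
        "between_coupling": model.between_coupling,
        "S": synchronizability(w).S if k.max() > 0 else 0.0,
    }
    try:
        gt["Q"] = modularity(w, model.module_assignment)
    except ValueError:
        gt["Q"] = np.nan
    return gt


def _plan_subjects(spec: CohortSpec) -> tuple[list[tuple[str, str, OscillatorModel]], list[SubjectRecord]]:
    """First pass: draw subject parameters and covariates (no signal yet)."""
    root = np.random.SeedSequence(spec.seed)
    meta_ss, rec_ss = root.spawn(2)
    meta_rng = np.random.default_rng(meta_ss)
    subject_seeds = [int(ss.generate_state(1)[0] % (2**31)) for ss in rec_ss.spawn(spec.n_subjects)]

    records: list[SubjectRecord] = []
    plans: list[tuple[str, str, OscillatorModel]] = []
    idx = 0
    for group, n_sub in spec.groups:
        jitters = np.exp(meta_rng.normal(0.0, spec.subject_sigma, size=n_sub))
        models = []
        truths = []
        for j in range(n_sub):
            m = _subject_model(spec, group, float(jitters[j]), subject_seeds[idx + j])
            models.append(m)
            truths.append(_ground_truth_metrics(m))
        base = _CLINICAL_BASELINES.get(group)
        is_control = group == spec.control_group or base is None

        # z-score each linked metric within the group so link slopes are
        # on a common scale
        def metric_z(name: str) -> np.ndarray:
            vals = np.array([t.get(name, np.nan) for t in truths], dtype=float)
            sd = vals.std()
            return (vals - vals.mean()) / sd if sd > 0 else np.zeros_like(vals)

        seiz = np.full(n_sub, np.nan)
        cog_shift = np.zeros(n_sub)
        if not is_control:
            lp = np.full(n_sub, base["log_seizure"])
            for link in spec.covariate_links:
                if link.target == "seizure_freq":
                    lp = lp + link.slope * metric_z(link.metric)
                    if link.noise_sd > 0:
                        lp = lp + meta_rng.normal(0.0, link.noise_sd, size=n_sub)
            seiz = np.exp(lp)
            for link in spec.covariate_links:
                if link.target == "cognition":
                    cog_shift = cog_shift + link.slope * metric_z(link.metric)
                    if link.noise_sd > 0:
                        cog_shift = cog_shift + meta_rng.normal(0.0, link.noise_sd, size=n_sub)
            dur = base["duration_median"] * np.exp(meta_rng.normal(0.0, 0.8, size=n_sub))
        else:
            dur = np.full(n_sub, np.nan)

        for j in range(n_sub):
            sid = f"{group}{j + 1:03d}"
            if is_control:
                cognition = {d: np.nan for d in COGNITIVE_DOMAINS}
                cog_avg = np.nan
            else:
                cognition = {
                    d: float(base["cognition"][d] + cog_shift[j]) for d in COGNITIVE_DOMAINS
                }
                cog_avg = float(np.mean(list(cognition.values())))
            records.append(
                SubjectRecord(
                    subject_id=sid,
                    group=group,
                    seizure_freq=float(seiz[j]),
                    epilepsy_duration=float(dur[j]),
                    cognition=cognition,
                    cognition_avg=cog_avg,
                    ground_truth=truths[j],
                    model=models[j],
                )
            )
            plans.append((sid, group, models[j]))
        idx += n_sub
    return plans, records


def iter_cohort(spec: CohortSpec) -> Iterator[tuple[EpochedRecording, SubjectRecord]]:
    """Generate the cohort subject by subject (memory-friendly)."""
    plans, records = _plan_subjects(spec)
    for (sid, _, model), record in zip(plans, records):
        rec = generate_recording(
            model, spec.n_epochs, spec.epoch_samples, subject_id=sid
        )
        yield rec, record


def generate_cohort(spec: CohortSpec) -> list[tuple[EpochedRecording, SubjectRecord]]:
    """Materialize the full cohort; bit-identical under the same seed."""
    return list(iter_cohort(spec))
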