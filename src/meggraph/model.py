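"""Model/Results interface over the full network-analysis pipeline.

:class:`CohortNetworkModel` holds a cohort (real or synthetic recordings
plus clinical metadata) and an :class:`AnalysisConfig`; ``fit()`` runs
band-pass filtering, PLI connectivity, surrogate-normalized graph metrics,
annealed modularity with node roles, and synchronizability for every
subject and band, and returns a :class:`CohortNetworkResults` carrying the
subject-metrics table, the partitions, the group statistics, and a
``summary()`` table of per-group means.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .connectivity import overall_pli, pli_matrix
from .graph_metrics import normalize_metrics
from .modularity import AnnealingSchedule, Partition, anneal_partition, participation
from .preprocessing import (
    EDGE_TRIM_FRACTION,
    EpochedRecording,
    band_by_name,
    bandpass,
    standard_bands,
    validate_epochs,
)
from .simulate import COGNITIVE_DOMAINS, CohortSpec, iter_cohort
from .stats import GroupAnalysis, StatsConfig, run_group_analysis
from .synchrony import synchronizability

__all__ = ["AnalysisConfig", "CohortNetworkModel", "CohortNetworkResults"]

METRIC_COLUMNS = ("pli", "cw_ratio", "lw_ratio", "S", "Q", "Pw", "zbar")


@dataclass
class AnalysisConfig:
    """Tunable parameters of one analysis run.

    Full-scale defaults follow the study protocol (1000 surrogates, the
    10^6-step annealing schedule, all seven bands); desk-scale work should
    override ``n_surrogates``, ``annealing_steps`` and ``bands``.
    """

    bands: tuple[str, ...] = tuple(b.name for b in standard_bands())
    n_surrogates: int = 1000
    annealing: AnnealingSchedule = field(default_factory=AnnealingSchedule)
    edge_trim: float = EDGE_TRIM_FRACTION
    amplitude_threshold: float | None = None  # None disables epoch rejection
    min_epochs: int = 1
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in self.bands:
            band_by_name(name)  # raises on unknown band names


def _substream(master_seed: int, *key: int) -> int:
    """Derive a named 31-bit substream seed from the master seed."""
    ss = np.random.SeedSequence([int(master_seed), *map(int, key)])
    return int(ss.generate_state(1)[0] % (2**31))


class CohortNetworkModel:
    """A cohort of multichannel recordings ready for network analysis.

    Parameters
    ----------
    recordings : list of EpochedRecording, optional
        One recording per subject. Mutually exclusive with ``spec``.
    metadata : DataFrame, optional
        One row per subject with ``subject_id``, ``group`` and any clinical
        covariates; required with ``recordings``.
    spec : CohortSpec, optional
        Generate the cohort on the fly (memory-friendly at full scale).
    config : AnalysisConfig
    """

    def __init__(
        self,
        recordings: list[EpochedRecording] | None = None,
        metadata: pd.DataFrame | None = None,
        spec: CohortSpec | None = None,
        config: AnalysisConfig | None = None,
    ) -> None:
        if (recordings is None) == (spec is None):
            raise ValueError("provide either recordings+metadata or a CohortSpec")
        if recordings is not None:
            if metadata is None:
                raise ValueError("metadata is required with explicit recordings")
            n_ch = {r.n_channels for r in recordings}
            if len(n_ch) > 1:
                raise ValueError(f"inconsistent channel counts across subjects: {sorted(n_ch)}")
        self.recordings = recordings
        self.metadata = metadata
        self.spec = spec
        self.config = config or AnalysisConfig()

    @classmethod
    def from_cohort_spec(
        cls, spec: CohortSpec, config: AnalysisConfig | None = None
    ) -> "CohortNetworkModel":
        return cls(spec=spec, config=config)

    @classmethod
    def from_directory(
        cls, path: str | Path, config: AnalysisConfig | None = None
    ) -> "CohortNetworkModel":
        recordings, metadata = mio.load_cohort(path)
        return cls(recordings=recordings, metadata=metadata, config=config)

    # -- fitting -------------------------------------------------------

    def _iter_subjects(self):
        if self.spec is not None:
            for rec, meta in iter_cohort(self.spec):
                row = {
                    "subject_id": meta.subject_id,
                    "group": meta.group,
                    "seizure_freq": meta.seizure_freq,
                    "epilepsy_duration": meta.epilepsy_duration,
                    "cognition": meta.cognition_avg,
                }
                for d in COGNITIVE_DOMAINS:
                    row[f"cognition_{d}"] = meta.cognition.get(d, np.nan)
                yield rec, row
        else:
            meta = self.metadata.set_index("subject_id", drop=False)
            for rec in self.recordings:
                row = meta.loc[rec.subject_id].to_dict()
                row.setdefault("seizure_freq", row.pop("seizure_freq_per_month", np.nan))
                row.setdefault(
                    "epilepsy_duration", row.pop("epilepsy_duration_months", np.nan)
                )
                row.setdefault("cognition", row.pop("cognition_avg", np.nan))
                yield rec, row

    def _analyze_subject(
        self, rec: EpochedRecording, subject_index: int
    ) -> tuple[list[dict], dict[str, Partition]]:
        cfg = self.config
        if cfg.amplitude_threshold is not None:
            rec = validate_epochs(rec, cfg.amplitude_threshold, cfg.min_epochs)
        rows = []
        partitions: dict[str, Partition] = {}
        for bi, band_name in enumerate(cfg.bands):
            band = band_by_name(band_name)
            filtered = bandpass(rec, band)
            cm = pli_matrix(filtered, edge_trim=cfg.edge_trim)
            w = cm.weights
            norm = normalize_metrics(
                w, cfg.n_surrogates, seed=_substream(cfg.seed, 1, subject_index, bi)
            )
            sched = replace(
                cfg.annealing, seed=_substream(cfg.seed, 2, subject_index, bi)
            )
            part = anneal_partition(w, sched)
            roles = participation(w, part)
            spec_res = synchronizability(w)
            partitions[band_name] = part
            rows.append(
                {
                    "band": band_name,
                    "n_epochs_used": cm.n_epochs_used,
                    "pli": overall_pli(cm),
                    "cw_ratio": norm.Cw_ratio,
                    "lw_ratio": norm.Lw_ratio,
                    "S": spec_res.S,
                    "Q": part.Q,
                    "Pw": roles.Pw,
                    "zbar": roles.Zbar,
                    "n_modules": part.n_modules,
                }
            )
        return rows, partitions

    def fit(self) -> "CohortNetworkResults":
        """Run the full analysis; deterministic given ``config.seed``."""
        all_rows: list[dict] = []
        partitions: dict[tuple[str, str], Partition] = {}
        for si, (rec, meta_row) in enumerate(self._iter_subjects()):
            rows, parts = self._analyze_subject(rec, si)
            for row in rows:
                out = dict(meta_row)
                out.update(row)
                all_rows.append(out)
            for band_name, part in parts.items():
                partitions[(rec.subject_id, band_name)] = part
        metrics = pd.DataFrame(all_rows)
        lead = ["subject_id", "group", "band"]
        metrics = metrics[lead + [c for c in metrics.columns if c not in lead]]
        return CohortNetworkResults(model=self, metrics=metrics, partitions=partitions)


def summarize(metrics: pd.DataFrame, band: str | None = None) -> pd.DataFrame:
    """Per-group mean of every network metric, metrics as rows, groups as columns.

    With ``band=None`` a (band, metric) row index is used.
    """
    if metrics.empty:
        raise ValueError("metrics table is empty")
    df = metrics if band is None else metrics[metrics["band"] == band]
    cols = [c for c in METRIC_COLUMNS if c in df.columns]
    out = df.groupby(["band", "group"])[cols].mean().T
    if band is not None:
        out.columns = out.columns.droplevel("band")
    return out


class CohortNetworkResults:
    """Fitted subject metrics, partitions, and group-level statistics."""

    def __init__(
        self,
        model: CohortNetworkModel,
        metrics: pd.DataFrame,
        partitions: dict[tuple[str, str], Partition],
    ) -> None:
        self.model = model
        self.metrics = metrics
        self.partitions = partitions
        self._analysis: GroupAnalysis | None = None

    def group_means(self, band: str | None = None) -> pd.DataFrame:
        return summarize(self.metrics, band=band)

    @property
    def group_analysis(self) -> GroupAnalysis:
        if self._analysis is None:
            self._analysis = run_group_analysis(self.metrics, self.model.config.stats)
        return self._analysis

    def summary(self) -> str:
        """Plain-text report: per-group means per band and the test outcomes."""
        lines = ["Cohort network analysis", "=" * 23, ""]
        n_sub = self.metrics["subject_id"].nunique()
        groups = self.metrics.groupby("group")["subject_id"].nunique()
        lines.append(
            f"Subjects: {n_sub} ({', '.join(f'{g}={n}' for g, n in groups.items())})"
        )
        lines.append(f"Bands: {', '.join(self.model.config.bands)}")
        lines.append("")
        for band in self.model.config.bands:
            lines.append(f"[{band}] group means")
            lines.append(self.group_means(band=band).round(4).to_string())
            lines.append("")
        ga = self.group_analysis
        lines.append("Omnibus tests (Kruskal-Wallis; FDR over the 5 network characteristics)")
        lines.append(ga.to_frame().round(4).to_string(index=False))
        if not ga.correlations.empty:
            lines.append("")
            lines.append("Within-group Kendall correlations")
            lines.append(ga.correlations.round(4).to_string(index=False))
        return "\n".join(lines)

    def plot_metric(self, metric: str, band: str, ax=None):
        """Group-wise strip/box plot of one metric in one band."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3.5))
        df = self.metrics[self.metrics["band"] == band]
        groups = sorted(df["group"].unique())
        data = [df.loc[df["group"] == g, metric].to_numpy() for g in groups]
        ax.boxplot(data, tick_labels=groups)
        for i, vals in enumerate(data, start=1):
            ax.plot(np.full(vals.size, i), vals, "o", alpha=0.5, ms=4)
        ax.set_ylabel(metric)
        ax.set_title(f"{metric} ({band} band)")
        return ax

    def save(self, outdir: str | Path) -> Path:
        """Write metrics, partitions, and test reports into ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.metrics.to_csv(outdir / "subject_metrics.tsv", sep="\t", index=False)
        part_dir = outdir / "partitions"
        part_dir.mkdir(exist_ok=True)
        for (sid, band), part in self.partitions.items():
            mio.write_partition(part, part_dir / f"{sid}_{band}.tsv", meta={"band": band})
        ga = self.group_analysis
        ga.to_frame().to_csv(outdir / "test_reports.tsv", sep="\t", index=False)
        ga.correlations.to_csv(outdir / "correlations.tsv", sep="\t", index=False)
        (outdir / "report.txt").write_text(self.summary() + "\n")
        return outdir
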