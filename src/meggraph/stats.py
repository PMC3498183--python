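"""Nonparametric group statistics for network metrics.

Network metrics are not normally distributed, so group differences are
tested per band with Kruskal-Wallis omnibus tests over the five network
characteristics (Cw ratio, Lw ratio, S, Q, Pw), corrected as a family with
the Benjamini-Hochberg false discovery rate. FDR-significant metrics are
followed up with pairwise Mann-Whitney U tests, and associations with
clinical covariates (seizure frequency, cognition) use Kendall's tau-b rank
correlation within groups. Mean functional connectivity (PLI) and the mean
within-module degree z-score are reported alongside but kept outside the
corrected family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatsConfig",
    "TestReport",
    "GroupAnalysis",
    "kruskal_wallis",
    "mann_whitney",
    "fdr_correct",
    "kendall_tau",
    "cognitive_z",
    "run_group_analysis",
]

#: the five network characteristics forming the FDR family
FAMILY_METRICS = ("cw_ratio", "lw_ratio", "S", "Q", "Pw")


def kruskal_wallis(samples: Sequence[np.ndarray]) -> tuple[float, float]:
    """Kruskal-Wallis H test across >= 2 groups, with tie correction.

    Returns (H, p) with p from the chi-square approximation on
    (groups - 1) degrees of freedom. All values identical across groups is
    a degenerate case with H = 0, p = 1.
    """
    groups = [np.asarray(s, dtype=float) for s in samples]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need >= 2 nonempty groups")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def mann_whitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns U = min(U_x, U_y).

    Uses the exact null distribution for small tie-free samples and the
    normal approximation with tie and continuity corrections otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    u_x = float(res.statistic)
    u = min(u_x, x.size * y.size - u_x)
    return u, float(res.pvalue)


def fdr_correct(p_values: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg linear step-up FDR correction.

    Returns (adjusted p-values, reject flags at level ``alpha``).
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a nonempty vector")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return p_adj, reject


def kendall_tau(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Kendall's tau-b with two-sided p-value.

    Requires equal lengths >= 3. Zero variance in either vector leaves tau
    undefined; (nan, nan) is returned as the flag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan, np.nan
    res = sps.kendalltau(x, y)
    return float(res.statistic), float(res.pvalue)


def cognitive_z(
    patient_scores: Mapping[str, Sequence[float]],
    control_mean: Mapping[str, Sequence[float]],
    control_sd: Mapping[str, Sequence[float]],
) -> tuple[dict[str, float], float]:
    """Cognitive z-scores against matched normative controls.

    Each domain maps to one or more subtest scores; every subtest score is
    converted to a z-score against the matched control mean and SD, subtests
    within a domain are averaged after conversion, and the overall score is
    the mean of the domain scores. Returns (per-domain z, overall z).
    """
    domain_z: dict[str, float] = {}
    for domain, scores in patient_scores.items():
        mu = np.asarray(control_mean[domain], dtype=float)
        sd = np.asarray(control_sd[domain], dtype=float)
        sc = np.asarray(scores, dtype=float)
        if np.any(sd <= 0):
            raise ValueError(f"domain {domain!r}: control SDs must be positive")
        domain_z[domain] = float(np.mean((sc - mu) / sd))
    overall = float(np.mean(list(domain_z.values())))
    return domain_z, overall


@dataclass
class StatsConfig:
    """Configuration of the group analysis."""

    alpha: float = 0.05
    family_metrics: tuple[str, ...] = FAMILY_METRICS
    extra_metrics: tuple[str, ...] = ("pli", "zbar")
    #: (metric, covariate) pairs correlated within each patient group
    covariate_pairs: tuple[tuple[str, str], ...] = (
        ("S", "seizure_freq"),
        ("S", "cognition"),
        ("Q", "cognition"),
    )


@dataclass
class TestReport:
    """Result of one omnibus test on one metric in one band."""

    metric: str
    band: str
    kw_statistic: float
    p_raw: float
    p_fdr: float
    significant: bool
    in_family: bool
    posthoc: list[tuple[tuple[str, str], float, float]] = field(default_factory=list)


@dataclass
class GroupAnalysis:
    """Omnibus + post-hoc reports and within-group covariate correlations."""

    reports: list[TestReport]
    correlations: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.reports:
            rows.append(
                {
                    "band": r.band,
                    "metric": r.metric,
                    "kw_statistic": r.kw_statistic,
                    "p_raw": r.p_raw,
                    "p_fdr": r.p_fdr,
                    "significant": r.significant,
                    "in_family": r.in_family,
                    "posthoc": "; ".join(
                        f"{a}-{b}: U={u:g}, p={p:.4g}" for (a, b), u, p in r.posthoc
                    ),
                }
            )
        return pd.DataFrame(rows)


def _group_values(df: pd.DataFrame, metric: str) -> list[np.ndarray]:
    return [sub[metric].to_numpy(dtype=float) for _, sub in df.groupby("group", sort=True)]


def run_group_analysis(table: pd.DataFrame, config: StatsConfig | None = None) -> GroupAnalysis:
    """Run the full per-band nonparametric analysis on a subject-metrics table.

    ``table`` needs one row per subject x band with columns ``subject_id``,
    ``group``, ``band``, the metric columns, and any covariates referenced by
    ``config.covariate_pairs``. Per band: Kruskal-Wallis over the family
    metrics, BH-FDR across that family, post-hoc pairwise Mann-Whitney tests
    for FDR-significant metrics only, uncorrected tests for the extra
    metrics, and within-group Kendall correlations for the configured
    metric-covariate pairs.
    """
    config = config or StatsConfig()
    for col in ("group", "band"):
        if col not in table.columns:
            raise KeyError(f"metrics table is missing required column {col!r}")
    groups = sorted(table["group"].unique())
    if len(groups) < 2:
        raise ValueError("group analysis requires at least 2 groups")
    for metric in config.family_metrics + config.extra_metrics:
        if metric not in table.columns:
            raise KeyError(f"metrics table is missing metric column {metric!r}")

    reports: list[TestReport] = []
    corr_rows = []
    for band, band_df in table.groupby("band", sort=False):
        # omnibus over the FDR family
        raw = []
        stats_ = []
        for metric in config.family_metrics:
            h, p = kruskal_wallis(_group_values(band_df, metric))
            stats_.append(h)
            raw.append(p)
        p_adj, reject = fdr_correct(np.asarray(raw), alpha=config.alpha)
        for metric, h, p, pa, rej in zip(config.family_metrics, stats_, raw, p_adj, reject):
            rep = TestReport(
                metric=metric,
                band=str(band),
                kw_statistic=h,
                p_raw=p,
                p_fdr=float(pa),
                significant=bool(rej),
                in_family=True,
            )
            if rep.significant:
                for ga, gb in combinations(groups, 2):
                    u, pp = mann_whitney(
                        band_df.loc[band_df["group"] == ga, metric],
                        band_df.loc[band_df["group"] == gb, metric],
                    )
                    rep.posthoc.append(((ga, gb), u, pp))
            reports.append(rep)
        # reported but uncorrected metrics
        for metric in config.extra_metrics:
            h, p = kruskal_wallis(_group_values(band_df, metric))
            reports.append(
                TestReport(
                    metric=metric,
                    band=str(band),
                    kw_statistic=h,
                    p_raw=p,
                    p_fdr=np.nan,
                    significant=bool(p < config.alpha),
                    in_family=False,
                )
            )
        # within-group covariate correlations
        for metric, covariate in config.covariate_pairs:
            if covariate not in band_df.columns:
                raise KeyError(f"metrics table is missing covariate column {covariate!r}")
            for grp, sub in band_df.groupby("group", sort=True):
                pair = sub[[metric, covariate]].dropna()
                if len(pair) < 3:
                    continue
                tau, p = kendall_tau(pair[metric].to_numpy(), pair[covariate].to_numpy())
                corr_rows.append(
                    {
                        "band": str(band),
                        "group": grp,
                        "metric": metric,
                        "covariate": covariate,
                        "n": len(pair),
                        "tau": tau,
                        "p": p,
                    }
                )
    return GroupAnalysis(reports=reports, correlations=pd.DataFrame(corr_rows))
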