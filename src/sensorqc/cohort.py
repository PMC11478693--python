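"""Participant-level metric aggregation, normalization and cohort statistics.

A cohort table has one row per (participant, sensor) carrying the eight
quality metrics plus the device label.  Per-record metrics (MDR, SNR, APD,
SRC, SCR) aggregate to the participant by the median over records; set-level
metrics (IRLR, RLC, VRC) are computed once per RecordSet.  All ratio metrics
are min-max normalized pooled over sensors and participants; SNR keeps its
dB scale.

Statistics follow the nonparametric stack: two-sided Mann-Whitney for
device contrasts, Kruskal-Wallis plus Dunn post hoc with Benjamini-Hochberg
FDR for covariate associations, and the epsilon-squared effect size
H/(n-1).  The Dunn z test is implemented here directly (standard rank-based
formula with tie correction).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import completeness, consistency, correctness
from .sensor_records import RecordSet, UndefinedMetricError

__all__ = [
    "DQM_COLUMNS",
    "RATIO_COLUMNS",
    "StatResult",
    "summarize_participant",
    "build_cohort_table",
    "minmax_normalize",
    "compare_devices",
    "covariate_association",
    "dunn_test",
]

logger = logging.getLogger(__name__)

DQM_COLUMNS = ("irlr", "scr", "mdr", "snr_db", "apd", "rlc", "src", "vrc")
RATIO_COLUMNS = tuple(c for c in DQM_COLUMNS if c != "snr_db")


@dataclass
class StatResult:
    metric: str
    grouping: str
    statistic: float
    p: float
    q: float
    effect_size: float | None = None
    group_stats: dict = field(default_factory=dict)


def summarize_participant(
    records: RecordSet,
    *,
    rounds: int = 8,
    seed: int = 0,
    aggregate: str = "median",
) -> dict[str, float]:
    """Aggregate one (participant, sensor) RecordSet into the eight metrics.

    Records failing a metric's precondition are excluded from that metric's
    aggregate; a value is NaN when no record qualifies.  ``aggregate`` may be
    "median" (default, matches the reported median/IQR summaries) or "mean".
    """
    if len(records) == 0:
        raise UndefinedMetricError("cannot summarize an empty RecordSet")
    agg = np.median if aggregate == "median" else np.mean
    out: dict[str, float] = {
        "participant_id": records.participant_id,
        "device_type": records.device_type,
        "sensor_type": records.sensor_type,
    }
    out["irlr"] = completeness.irlr(records)
    try:
        exp_ch = completeness.escc(records)
        scrs = [completeness.scr(r, exp_ch) for r in records]
        out["scr"] = float(agg(scrs)) if scrs else np.nan
    except UndefinedMetricError:
        out["scr"] = np.nan
    mdrs, snrs, srcs = [], [], []
    apds = []
    rng = np.random.default_rng(seed)
    for rec in records:
        if rec.length >= 2:
            try:
                mdrs.append(completeness.mdr(rec)[0])
            except UndefinedMetricError:
                pass
            snrs.append(correctness.snr_db(rec))
        if rec.length >= 3:
            try:
                srcs.append(consistency.src(rec))
            except UndefinedMetricError:
                pass
        if rec.length >= correctness.MIN_POINTS_FOR_SCORING:
            ds = correctness.anomaly_scores(rec, rounds=rounds, seed=rng)
            apds.append(correctness.apd(rec, ds)[0])
    out["mdr"] = float(agg(mdrs)) if mdrs else np.nan
    out["snr_db"] = float(agg(snrs)) if snrs else np.nan
    out["apd"] = float(agg(apds)) if apds else np.nan
    out["src"] = float(agg(srcs)) if srcs else np.nan
    interpretable = RecordSet([r for r in records if r.length > 1])
    if len(interpretable):
        out["rlc"] = consistency.rlc(interpretable)
        try:
            out["vrc"] = consistency.vrc(interpretable)
        except UndefinedMetricError:
            out["vrc"] = np.nan
    else:
        out["rlc"] = np.nan
        out["vrc"] = np.nan
    return out


def build_cohort_table(
    cohort: dict[tuple[str, str], RecordSet],
    *,
    rounds: int = 8,
    seed: int = 0,
    aggregate: str = "median",
) -> pd.DataFrame:
    """Cohort table: one row of metrics per (participant, sensor)."""
    rows = [
        summarize_participant(rs, rounds=rounds, seed=seed, aggregate=aggregate)
        for rs in cohort.values()
    ]
    df = pd.DataFrame(rows)
    return df[["participant_id", "device_type", "sensor_type", *DQM_COLUMNS]]


def minmax_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Min-max scale each ratio metric pooled over all rows; SNR untouched.

    A zero-range column maps to all zeros.  Idempotent.
    """
    if len(table) < 2:
        raise ValueError("normalization needs at least 2 rows")
    out = table.copy()
    for col in RATIO_COLUMNS:
        x = out[col].to_numpy(dtype=float)
        lo, hi = np.nanmin(x), np.nanmax(x)
        out[col] = np.zeros_like(x) if hi == lo else (x - lo) / (hi - lo)
        out.loc[table[col].isna(), col] = np.nan
    return out


def _group_stats(values: np.ndarray) -> dict[str, float]:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return {"median": float(med), "iqr": float(q3 - q1), "n": int(values.size)}


def compare_devices(table: pd.DataFrame, metric: str) -> StatResult:
    """Two-sided Mann-Whitney U (normal approximation, tie-corrected) of one
    metric between Android and iOS rows, with per-group median and IQR."""
    groups = {}
    for dev in ("android", "ios"):
        v = table.loc[table["device_type"] == dev, metric].dropna().to_numpy()
        if v.size < 2:
            raise ValueError(f"device group {dev!r} has < 2 values for {metric}")
        groups[dev] = v
    res = stats.mannwhitneyu(
        groups["android"], groups["ios"], alternative="two-sided", method="asymptotic"
    )
    return StatResult(
        metric=metric,
        grouping="device_type",
        statistic=float(res.statistic),
        p=float(res.pvalue),
        q=float(res.pvalue),
        group_stats={d: _group_stats(v) for d, v in groups.items()},
    )


def dunn_test(groups: list[np.ndarray]) -> np.ndarray:
    """Dunn's post-hoc pairwise z tests after Kruskal-Wallis.

    Returns a condensed array of two-sided p-values for all group pairs in
    ``itertools.combinations`` order, using pooled ranks with tie correction.
    """
    k = len(groups)
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks = []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start : start + g.size].mean())
        start += g.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term
    ps = []
    for i, j in itertools.combinations(range(k), 2):
        se = np.sqrt(var_base * (1.0 / groups[i].size + 1.0 / groups[j].size))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        ps.append(2.0 * stats.norm.sf(abs(z)))
    return np.asarray(ps)


def covariate_association(
    table: pd.DataFrame,
    covariate: str,
    metrics: tuple[str, ...] = DQM_COLUMNS,
    alpha: float = 0.05,
) -> list[StatResult]:
    """Kruskal-Wallis per metric across covariate levels, Dunn post hoc with
    Benjamini-Hochberg correction over all pairwise tests of the metric's
    family, and the epsilon-squared effect size H/(n-1)."""
    results: list[StatResult] = []
    for metric in metrics:
        sub = table[[covariate, metric]].dropna()
        levels = []
        names = []
        for lvl, grp in sub.groupby(covariate, observed=True):
            v = grp[metric].to_numpy(dtype=float)
            if v.size < 2:
                logger.warning("level %r dropped for %s (<2 observations)", lvl, metric)
                continue
            levels.append(v)
            names.append(lvl)
        if len(levels) < 2:
            raise ValueError(f"covariate {covariate!r} has < 2 usable levels")
        h, p = stats.kruskal(*levels)
        n = sum(v.size for v in levels)
        eps2 = float(h) / (n - 1)
        pair_ps = dunn_test(levels)
        _, qs, _, _ = multipletests(pair_ps, alpha=alpha, method="fdr_bh")
        pair_stats = {
            f"{a}|{b}": {"p": float(pp), "q": float(qq)}
            for (a, b), pp, qq in zip(
                itertools.combinations(names, 2), pair_ps, qs
            )
        }
        results.append(
            StatResult(
                metric=metric,
                grouping=covariate,
                statistic=float(h),
                p=float(p),
                q=float(p),  # omnibus q filled below across metrics
                effect_size=eps2,
                group_stats={
                    "levels": {
                        str(nm): _group_stats(v) for nm, v in zip(names, levels)
                    },
                    "pairwise": pair_stats,
                },
            )
        )
    _, omnibus_q, _, _ = multipletests(
        [r.p for r in results], alpha=alpha, method="fdr_bh"
    )
    for r, q in zip(results, omnibus_q):
        r.q = float(q)
    return results
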