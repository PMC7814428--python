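"""Nonparametric analysis of the replicated bench measurements.

Replicate counts are small (n = 10 per cell) and the scatter is not
reliably normal, so group comparisons use the Kruskal-Wallis rank test:
across correction angles within each SPOI group, and across the four
SPOI groups within each correction angle.  A Shapiro-Wilk screen per
cell documents the nonparametric choice but never gates the pipeline.
p-values use the tie-corrected chi-square approximation; an exhaustive
permutation alternative is provided for small designs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "RankTestResult",
    "AnalysisReport",
    "ranks_with_ties",
    "kruskal_wallis",
    "kruskal_wallis_exact",
    "normality_screen",
    "analyze_table",
    "render_report",
]


@dataclass(frozen=True)
class RankTestResult:
    h_statistic: float
    df: int
    p_value: float
    group_sizes: tuple[int, ...]


@dataclass(frozen=True)
class AnalysisReport:
    """Both p-value margins of the bench table plus normality flags.

    per_spoi : p-value of the Kruskal-Wallis test across correction-angle
        groups, one per SPOI.
    per_correction : p-value across the four SPOI groups, one per
        correction angle.
    normality_nonnormal : per-cell flag, True where Shapiro-Wilk p < 0.05
        (NaN-flagged cells were degenerate or out of range and skipped).
    alpha : significance level used for flagging.
    """

    per_spoi: pd.Series
    per_correction: pd.Series
    per_spoi_h: pd.Series
    per_correction_h: pd.Series
    normality_nonnormal: pd.DataFrame
    alpha: float = 0.05

    def significant_spois(self) -> list[float]:
        return [s for s, p in self.per_spoi.items() if p < self.alpha]


def ranks_with_ties(values) -> np.ndarray:
    """Mid-ranks of ``values`` (ties share the average rank).

    Rank sum is always n(n+1)/2.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot rank an empty sequence")
    return scipy.stats.rankdata(v, method="average")


def _h_statistic(groups: list[np.ndarray]) -> float:
    """Tie-corrected Kruskal-Wallis H."""
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = ranks_with_ties(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + g.size]
        h += g.size * (r.mean() - (n + 1) / 2.0) ** 2
        start += g.size
    h *= 12.0 / (n * (n + 1))
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    if tie == 0.0:  # all observations identical
        return 0.0
    return h / tie


def kruskal_wallis(groups) -> RankTestResult:
    """Kruskal-Wallis rank test across k groups.

    H = 12/(N(N+1)) Σ nᵢ(R̄ᵢ − (N+1)/2)², divided by the tie correction
    1 − Σ(t³−t)/(N³−N); p from the chi-square upper tail with k−1 df.
    A fully-tied sample returns H = 0, p = 1 rather than erroring.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size == 0 for g in gs):
        raise ValueError("every group needs at least 1 observation")
    sizes = tuple(g.size for g in gs)
    if sum(sizes) < 3:
        raise ValueError("need at least 3 observations in total")
    df = len(gs) - 1
    pooled = np.concatenate(gs)
    if np.all(pooled == pooled[0]):
        return RankTestResult(0.0, df, 1.0, sizes)
    h, p = scipy.stats.kruskal(*gs)
    return RankTestResult(float(h), df, float(p), sizes)


def kruskal_wallis_exact(groups, max_permutations: int = 500_000) -> RankTestResult:
    """Exact permutation p-value for small designs.

    Enumerates every assignment of the pooled observations to the group
    sizes (multinomial coefficient) and reports the fraction with
    H ≥ H_observed.  Refuses designs larger than ``max_permutations``
    arrangements.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    sizes = tuple(g.size for g in gs)
    n = sum(sizes)
    n_arrangements = math.factorial(n)
    for s in sizes:
        n_arrangements //= math.factorial(s)
    if n_arrangements > max_permutations:
        raise ValueError(f"{n_arrangements} arrangements exceed the exact-test limit")
    pooled = np.concatenate(gs)
    h_obs = _h_statistic(gs)
    count = 0
    total = 0
    idx = np.arange(n)
    for combo in _partitions(idx, sizes):
        total += 1
        perm_groups = [pooled[list(c)] for c in combo]
        if _h_statistic(perm_groups) >= h_obs - 1e-12:
            count += 1
    return RankTestResult(float(h_obs), len(gs) - 1, count / total, sizes)


def _partitions(idx: np.ndarray, sizes: tuple[int, ...]):
    """All ways to split ``idx`` into ordered groups of the given sizes."""
    if len(sizes) == 1:
        yield (tuple(idx),)
        return
    for head in itertools.combinations(idx, sizes[0]):
        rest = np.array(sorted(set(idx) - set(head)))
        for tail in _partitions(rest, sizes[1:]):
            yield (head,) + tail


def normality_screen(trials: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Shapiro-Wilk screen per (correction, SPOI) cell.

    Returns a correction x SPOI frame: True = non-normal (p < alpha),
    False = no evidence against normality, NaN = degenerate (constant
    cell) or replicate count outside [3, 50], skipped.
    """
    flags = {}
    for (phi, th), cell in trials.groupby(["spoi_deg", "correction_deg"]):
        v = cell["slope_deg"].to_numpy()
        if not 3 <= v.size <= 50 or np.all(v == v[0]):
            flags[(th, phi)] = np.nan
            continue
        _, p = scipy.stats.shapiro(v)
        flags[(th, phi)] = bool(p < alpha)
    s = pd.Series(flags)
    s.index.names = ["correction_deg", "spoi_deg"]
    return s.unstack("spoi_deg")


def analyze_table(trials: pd.DataFrame, alpha: float = 0.05) -> AnalysisReport:
    """Both Kruskal-Wallis margins of a full trial table.

    Per SPOI: test across the non-trivial correction angles (θ = 0° is
    excluded — it is the uncorrected state).  Per correction angle
    (again excluding 0°): test across the SPOI groups.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    work = trials[trials["correction_deg"] > 0.0]
    spois = list(dict.fromkeys(work["spoi_deg"]))
    corrections = sorted(work["correction_deg"].unique())
    counts = work.groupby(["spoi_deg", "correction_deg"])["slope_deg"].count()
    expected = {(s, t) for s in spois for t in corrections}
    if set(counts.index) != expected:
        raise ValueError("trial table does not cover the full SPOI x correction grid")

    def cell(phi, th):
        m = (work["spoi_deg"] == phi) & (work["correction_deg"] == th)
        return work.loc[m, "slope_deg"].to_numpy()

    spoi_res = {phi: kruskal_wallis([cell(phi, th) for th in corrections]) for phi in spois}
    corr_res = {th: kruskal_wallis([cell(phi, th) for phi in spois]) for th in corrections}
    return AnalysisReport(
        per_spoi=pd.Series({k: r.p_value for k, r in spoi_res.items()}, name="p_value"),
        per_correction=pd.Series({k: r.p_value for k, r in corr_res.items()}, name="p_value"),
        per_spoi_h=pd.Series({k: r.h_statistic for k, r in spoi_res.items()}, name="h"),
        per_correction_h=pd.Series({k: r.h_statistic for k, r in corr_res.items()}, name="h"),
        normality_nonnormal=normality_screen(trials, alpha=alpha),
        alpha=alpha,
    )


def _fmt_p(p: float) -> str:
    return "< 0.001" if p < 0.001 else f"{p:.3f}"


def render_report(trials: pd.DataFrame, report: AnalysisReport) -> str:
    """Text rendering of the bench-table layout.

    Mean ± SD per cell, a p-value column per row (across SPOI groups)
    and a p-value row per column (across correction angles); p below
    0.001 prints as "< 0.001".
    """
    work = trials[trials["correction_deg"] > 0.0]
    spois = list(report.per_spoi.index)
    corrections = list(report.per_correction.index)
    g = work.groupby(["correction_deg", "spoi_deg"])["slope_deg"]
    mean, sd = g.mean(), g.std(ddof=1)
    n = int(work.groupby(["correction_deg", "spoi_deg"])["slope_deg"].count().iloc[0])

    header = ["Correction"] + [f"SPOI {s:g}°" for s in spois] + ["P-value"]
    lines = [f"Posterior slope by SPOI and correction angle (n = {n})", "\t".join(header)]
    for th in corrections:
        row = [f"{th:g}°"]
        row += [f"{mean[(th, s)]:.1f} ± {sd[(th, s)]:.1f}°" for s in spois]
        row.append(_fmt_p(report.per_correction[th]))
        lines.append("\t".join(row))
    lines.append("\t".join(["P-value"] + [_fmt_p(report.per_spoi[s]) for s in spois] + [""]))
    lines.append("P-values: Kruskal-Wallis test; significance at "
                 f"alpha = {report.alpha:g}.")
    return "\n".join(lines) + "\n"
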