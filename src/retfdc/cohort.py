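"""Nonparametric case/control statistics for fractal-dimension tables.

Two-group comparisons follow the classical rank-based toolkit: the
tie-corrected Kruskal-Wallis H test with per-group standardised average
ranks, and the Mann-Whitney (Wilcoxon rank-sum) confidence interval for the
difference in population medians, whose point estimate is the
Hodges-Lehmann median of all pairwise between-group differences.

Formulas (midranks for ties, N pooled observations in g groups of sizes
n_j with rank sums R_j and t tied values per tie group):

    H = [ 12 / (N (N+1)) * sum_j R_j^2 / n_j - 3 (N+1) ]
        / [ 1 - sum_t (t^3 - t) / (N^3 - N) ]
    z_j = (Rbar_j - (N+1)/2) / sqrt( (N+1)(N - n_j) / (12 n_j) )

with p from the chi-square distribution on g-1 degrees of freedom.  The CI
endpoints are order statistics of the sorted pairwise differences at ranks
derived from the exact Mann-Whitney U null distribution (normal
approximation once m*n exceeds ``exact_max``).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, rankdata

from .errors import ParameterError
from .scanpath import COMBO_ORDER

__all__ = [
    "GroupSummary",
    "KruskalWallisResult",
    "MannWhitneyCI",
    "kruskal_wallis",
    "mann_whitney_ci",
    "cohort_report",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroupSummary:
    """Per-group summary line: size, median, average rank, z-score."""

    n: int
    median: float
    avg_rank: float
    z: float


@dataclass(frozen=True)
class KruskalWallisResult:
    """Tie-corrected Kruskal-Wallis outcome with per-group summaries."""

    H: float
    p: float
    df: int
    groups: dict[str, GroupSummary]


@dataclass(frozen=True)
class MannWhitneyCI:
    """Hodges-Lehmann shift estimate with its rank-based confidence interval."""

    point_estimate: float
    ci_low: float
    ci_high: float
    confidence: float
    achieved_confidence: float


def kruskal_wallis(values_by_group: dict[str, np.ndarray]) -> KruskalWallisResult:
    """Kruskal-Wallis one-way analysis of variance by ranks.

    Accepts two or more groups (each n >= 2); ties receive midranks and the
    H statistic is divided by the usual tie-correction factor.  When every
    pooled value is identical the test degenerates to H = 0, p = 1 with a
    warning.
    """
    labels = list(values_by_group)
    if len(labels) < 2:
        raise ParameterError("need at least two groups")
    arrays = [np.asarray(values_by_group[k], dtype=np.float64).ravel() for k in labels]
    sizes = [a.size for a in arrays]
    if any(n < 2 for n in sizes):
        raise ParameterError("every group needs at least 2 observations")
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = rankdata(pooled)
    # tie correction over pooled midrank groups
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    denom = 1.0 - tie_term / (n_total**3 - n_total)
    bounds = np.cumsum([0] + sizes)
    rank_sums = [ranks[bounds[i] : bounds[i + 1]].sum() for i in range(len(labels))]
    h_raw = 12.0 / (n_total * (n_total + 1)) * sum(
        rs**2 / n for rs, n in zip(rank_sums, sizes)
    ) - 3.0 * (n_total + 1)
    if denom <= 0.0:
        warnings.warn("all pooled values identical; H = 0, p = 1", stacklevel=2)
        h_stat, p = 0.0, 1.0
    else:
        h_stat = h_raw / denom
        h_stat = max(h_stat, 0.0)
        p = float(chi2.sf(h_stat, len(labels) - 1))
    groups = {}
    for lab, arr, rs, n in zip(labels, arrays, rank_sums, sizes):
        avg = rs / n
        z = (avg - (n_total + 1) / 2.0) / np.sqrt(
            (n_total + 1) * (n_total - n) / (12.0 * n)
        )
        groups[lab] = GroupSummary(n=n, median=float(np.median(arr)), avg_rank=float(avg), z=float(z))
    return KruskalWallisResult(H=float(h_stat), p=p, df=len(labels) - 1, groups=groups)


@lru_cache(maxsize=64)
def _mwu_cdf(m: int, n: int) -> np.ndarray:
    """Exact null CDF of the Mann-Whitney U statistic for sample sizes m, n.

    Counts subsets of size m of ranks 1..m+n by rank sum via dynamic
    programming; U = W - m(m+1)/2.  Counts are float64, adequate to well
    below the tail probabilities used for CI ranks.
    """
    total = m + n
    max_w = m * n + m * (m + 1) // 2
    dp = np.zeros((m + 1, max_w + 1))
    dp[0, 0] = 1.0
    for i in range(1, total + 1):
        kmax = min(i, m)
        for k in range(kmax, 0, -1):
            dp[k, i:] += dp[k - 1, : max_w + 1 - i]
    counts = dp[m, m * (m + 1) // 2 :]
    return np.cumsum(counts) / counts.sum()


def mann_whitney_ci(
    case_values: np.ndarray,
    control_values: np.ndarray,
    confidence: float = 0.95,
    exact_max: int = 10_000,
) -> MannWhitneyCI:
    """Mann-Whitney CI for the shift case - control, with Hodges-Lehmann point.

    All m*n pairwise differences case_i - control_j are formed; the point
    estimate is their median and the CI endpoints are the k-th smallest and
    k-th largest difference, where k is the largest integer with
    P(U <= k-1) <= alpha/2 under the exact U null distribution (normal
    approximation with continuity correction when m*n > ``exact_max``).
    The confidence actually achieved by the exact rank is reported.
    """
    case = np.asarray(case_values, dtype=np.float64).ravel()
    control = np.asarray(control_values, dtype=np.float64).ravel()
    m, n = case.size, control.size
    if m < 2 or n < 2:
        raise ParameterError("each sample needs at least 2 observations")
    if not 0.5 < confidence < 1.0:
        raise ParameterError("confidence must be in (0.5, 1)")
    diffs = np.sort(np.subtract.outer(case, control).ravel())
    point = float(np.median(diffs))
    mn = m * n
    alpha = 1.0 - confidence
    if diffs[0] == diffs[-1]:
        warnings.warn("all pairwise differences tied; zero-width CI", stacklevel=2)
        return MannWhitneyCI(point, point, point, confidence, 1.0)
    if mn <= exact_max:
        cdf = _mwu_cdf(m, n)
        # largest k with P(U <= k-1) <= alpha/2
        k = int(np.searchsorted(cdf, alpha / 2.0, side="right"))
        if k < 1:
            warnings.warn(
                "samples too small for the requested confidence; using widest interval",
                stacklevel=2,
            )
            k = 1
            achieved = 1.0 - 2.0 * float(cdf[0])
        else:
            achieved = 1.0 - 2.0 * float(cdf[k - 1])
    else:
        z = norm.ppf(1.0 - alpha / 2.0)
        mu = mn / 2.0
        sd = np.sqrt(mn * (m + n + 1) / 12.0)
        k = max(1, int(np.floor(mu - z * sd + 0.5)))
        achieved = confidence
    return MannWhitneyCI(
        point_estimate=point,
        ci_low=float(diffs[k - 1]),
        ci_high=float(diffs[mn - k]),
        confidence=confidence,
        achieved_confidence=achieved,
    )


_REPORT_COLUMNS = [
    "method",
    "zone",
    "n_control",
    "median_control",
    "avg_rank_control",
    "z_control",
    "n_case",
    "median_case",
    "avg_rank_case",
    "z_case",
    "hl_shift",
    "ci_low",
    "ci_high",
    "H",
    "p",
]


def _zone_sort_key(zone: str) -> tuple[int, str]:
    try:
        return (COMBO_ORDER.index(zone), zone)
    except ValueError:
        return (len(COMBO_ORDER), zone)


def cohort_report(
    table: pd.DataFrame,
    confidence: float = 0.95,
    holm: bool = False,
) -> pd.DataFrame:
    """Per-(method, zone) rank-test report for a long-form FD table.

    ``table`` has columns subject_id, group (case/control), method, zone,
    fd_value, with one value per subject x method x zone.  Each complete
    (method, zone) cell yields one report row with group medians, average
    ranks, z-scores, the Hodges-Lehmann shift and its CI, and the
    Kruskal-Wallis H and p.  Incomplete cells are skipped with a log entry.
    ``holm`` adds a Holm-adjusted p-value column across the report's rows
    (the primary analysis applies no multiplicity correction).
    """
    required = {"subject_id", "group", "method", "zone", "fd_value"}
    if not required.issubset(table.columns):
        raise ParameterError(f"table must have columns {sorted(required)}")
    bad_groups = set(table["group"]) - {"case", "control"}
    if bad_groups:
        raise ParameterError(f"unknown group labels: {sorted(bad_groups)}")
    dup = table.duplicated(subset=["subject_id", "method", "zone"])
    if dup.any():
        raise ParameterError("duplicate subject x method x zone rows")
    rows = []
    keys = sorted(
        table.groupby(["method", "zone"]).groups,
        key=lambda mz: (mz[0], _zone_sort_key(mz[1])),
    )
    for method, zone in keys:
        cell = table[(table["method"] == method) & (table["zone"] == zone)]
        cell = cell.dropna(subset=["fd_value"])
        case = cell.loc[cell["group"] == "case", "fd_value"].to_numpy()
        control = cell.loc[cell["group"] == "control", "fd_value"].to_numpy()
        if case.size < 2 or control.size < 2:
            log.warning("skipping %s/%s: fewer than 2 values per group", method, zone)
            continue
        kw = kruskal_wallis({"control": control, "case": case})
        ci = mann_whitney_ci(case, control, confidence=confidence)
        rows.append(
            {
                "method": method,
                "zone": zone,
                "n_control": kw.groups["control"].n,
                "median_control": kw.groups["control"].median,
                "avg_rank_control": kw.groups["control"].avg_rank,
                "z_control": kw.groups["control"].z,
                "n_case": kw.groups["case"].n,
                "median_case": kw.groups["case"].median,
                "avg_rank_case": kw.groups["case"].avg_rank,
                "z_case": kw.groups["case"].z,
                "hl_shift": ci.point_estimate,
                "ci_low": ci.ci_low,
                "ci_high": ci.ci_high,
                "H": kw.H,
                "p": kw.p,
            }
        )
    report = pd.DataFrame(rows, columns=_REPORT_COLUMNS)
    if holm and len(report):
        order = np.argsort(report["p"].to_numpy())
        m_tests = len(report)
        adj = np.empty(m_tests)
        running = 0.0
        for rank_i, idx in enumerate(order):
            running = max(running, (m_tests - rank_i) * report["p"].iloc[idx])
            adj[idx] = min(1.0, running)
        report["p_holm"] = adj
    return report
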