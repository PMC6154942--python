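"""Elementary statistics used throughout the pipeline.

The four primitives every stage leans on — Wilcoxon rank-sum, Pearson
chi-square, Spearman rank correlation and Benjamini–Hochberg FDR adjustment —
are implemented here from first principles (rank handling, tie corrections,
exact small-sample enumeration) so that their behaviour is fully specified by
this module rather than by a third-party default. Reference distributions
(normal, chi-square, t) come from :mod:`scipy.stats`.

All tests return a :class:`TestResult`; p-values live in ``(0, 1]``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

__all__ = [
    "TestResult",
    "midrank",
    "wilcoxon_rank_sum",
    "chi_square",
    "spearman",
    "bh_adjust",
    "welch_t",
    "format_percent",
    "cohort_summary",
]

#: above this combined sample size the rank-sum test switches from exact
#: enumeration to the tie-corrected normal approximation
EXACT_LIMIT = 25


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-group test."""

    statistic: float
    p: float
    n1: int
    n2: int

    def __post_init__(self) -> None:
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"p-value {self.p} outside (0, 1]")


def midrank(values: np.ndarray) -> np.ndarray:
    """Midranks (1-based); tied values share the average of their ranks."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), dtype=float)
    sorted_vals = values[order]
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _exact_ranksum_pvalue(ranks: np.ndarray, n1: int, w_obs: float) -> float:
    """Two-sided exact p for the rank-sum W of group 1.

    Dynamic programme over the multiset of (doubled, hence integer) midranks:
    ``dp[k][s]`` counts subsets of size ``k`` with doubled-rank sum ``s``.
    Equivalent to enumerating all C(N, n1) group assignments.
    """
    doubled = np.round(2.0 * ranks).astype(int)
    total = int(doubled.sum())
    dp = np.zeros((n1 + 1, total + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in doubled:
        for k in range(min(n1, 1_000), 0, -1):
            dp[k, r:] += dp[k - 1, : total + 1 - r]
    dist = dp[n1]
    n_total = dist.sum()
    w2 = int(round(2.0 * w_obs))
    lower = dist[: w2 + 1].sum() / n_total
    upper = dist[w2:].sum() / n_total
    return min(1.0, 2.0 * min(lower, upper))


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Two-sided Wilcoxon (Mann–Whitney) rank-sum test.

    Midranks for ties. Exact enumeration of all group assignments when
    ``n1 + n2 <= 25``; otherwise the normal approximation with tie and
    continuity corrections. The statistic is the rank sum of ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("wilcoxon_rank_sum requires both groups non-empty")
    n1, n2 = x.size, y.size
    n = n1 + n2
    ranks = midrank(np.concatenate([x, y]))
    w = float(ranks[:n1].sum())

    if n <= EXACT_LIMIT:
        p = _exact_ranksum_pvalue(ranks, n1, w)
        return TestResult(statistic=w, p=max(p, np.finfo(float).tiny), n1=n1, n2=n2)

    mu = n1 * (n + 1) / 2.0
    # tie correction to the rank-sum variance
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(((counts**3 - counts)).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # every observation identical
        return TestResult(statistic=w, p=1.0, n1=n1, n2=n2)
    z = (abs(w - mu) - 0.5) / math.sqrt(var)
    p = min(1.0, 2.0 * float(_sps.norm.sf(z)))
    return TestResult(statistic=w, p=max(p, np.finfo(float).tiny), n1=n1, n2=n2)


def chi_square(table, yates: bool = False) -> TestResult:
    """Pearson chi-square test of independence on an r x c count table.

    No continuity correction by default; ``yates=True`` applies the Yates
    correction (2x2 only). All row and column marginals must be positive.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("chi_square requires all marginals > 0")
    expected = np.outer(row, col) / obs.sum()
    diff = np.abs(obs - expected)
    if yates:
        if obs.shape != (2, 2):
            raise ValueError("Yates correction applies to 2x2 tables only")
        diff = np.maximum(diff - 0.5, 0.0)
    x2 = float((diff**2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(_sps.chi2.sf(x2, df))
    return TestResult(
        statistic=x2,
        p=max(min(p, 1.0), np.finfo(float).tiny),
        n1=int(row[0]),
        n2=int(row[1:].sum()),
    )


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (midranks) with t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("spearman requires n >= 3")
    rx, ry = midrank(x), midrank(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0.0 or sy == 0.0:
        raise ValueError("spearman undefined for a constant vector")
    rho = float(np.clip(((rx - rx.mean()) * (ry - ry.mean())).mean() / (sx * sy), -1.0, 1.0))
    if abs(rho) == 1.0:
        p = np.finfo(float).tiny
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = min(1.0, 2.0 * float(_sps.t.sf(abs(t), n - 2)))
    return rho, max(p, np.finfo(float).tiny)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    ``q_(i) = min_{j >= i} m * p_(j) / j`` on the sorted p-values, capped at
    one and mapped back to the input order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def welch_t(x, y) -> TestResult:
    """Welch's unequal-variance t test (two-sided)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("welch_t requires n >= 2 per group")
    v1, v2 = x.var(ddof=1) / x.size, y.var(ddof=1) / y.size
    se = math.sqrt(v1 + v2)
    if se == 0.0:
        return TestResult(statistic=0.0, p=1.0, n1=x.size, n2=y.size)
    t = float((x.mean() - y.mean()) / se)
    df = (v1 + v2) ** 2 / (v1**2 / (x.size - 1) + v2**2 / (y.size - 1))
    p = min(1.0, 2.0 * float(_sps.t.sf(abs(t), df)))
    return TestResult(statistic=t, p=max(p, np.finfo(float).tiny), n1=x.size, n2=y.size)


def format_percent(count: int, total: int) -> str:
    """One-decimal percentage, round half away from zero (survey convention)."""
    if total <= 0:
        raise ValueError("total must be positive")
    pct = 100.0 * count / total
    scaled = pct * 10.0
    rounded = math.floor(scaled + 0.5) if scaled >= 0 else math.ceil(scaled - 0.5)
    return f"{rounded / 10.0:.1f}"


# cohort columns summarised as count (%) rows, in display order
_FLAG_ROWS = [
    ("waist_flag", "Waist >= 90 cm (male) or >= 85 cm (female)"),
    ("bp_flag", "BP >= 130/85 mmHg"),
    ("sbp_flag", "SBP >= 130 mmHg"),
    ("dbp_flag", "DBP >= 85 mmHg"),
    ("tg_flag", "TG >= 1.7 mmol/L"),
    ("hdl_flag", "HDL < 1.04 mmol/L"),
    ("fbg_flag", "FBG >= 6.1 mmol/L"),
    ("mets", "MetS"),
]


def cohort_summary(cohort: pd.DataFrame) -> pd.DataFrame:
    """Participant-characteristics table by gender.

    One row per MetS component plus age: counts with one-decimal percentages
    per gender, Welch's t test for age, chi-square for every flag. A
    single-gender cohort yields the summary without tests (p column NaN).
    """
    import warnings

    if "gender" not in cohort.columns:
        raise ValueError("cohort must contain a 'gender' column")
    genders = [g for g in ("female", "male") if (cohort["gender"] == g).any()]
    if not genders:
        raise ValueError("cohort contains no recognised gender levels")
    two_groups = len(genders) == 2
    if not two_groups:
        warnings.warn("single-gender cohort: group tests omitted", stacklevel=2)

    rows = []
    sub = {g: cohort[cohort["gender"] == g] for g in genders}
    age_cells = {
        g: f"{sub[g]['age'].mean():.1f} ± {sub[g]['age'].std(ddof=1):.1f}"
        for g in genders
    }
    age_p = (
        welch_t(sub["female"]["age"].to_numpy(), sub["male"]["age"].to_numpy()).p
        if two_groups
        else float("nan")
    )
    rows.append({"characteristic": "Age (years, mean ± SD)", **age_cells, "p": age_p})

    for col, label in _FLAG_ROWS:
        if col not in cohort.columns:
            continue
        cells = {}
        counts = {}
        for g in genders:
            k = int(sub[g][col].sum())
            n = len(sub[g])
            counts[g] = (k, n)
            cells[g] = f"{k} ({format_percent(k, n)})"
        if two_groups:
            k1, n1 = counts["female"]
            k2, n2 = counts["male"]
            p = chi_square([[k1, n1 - k1], [k2, n2 - k2]]).p
        else:
            p = float("nan")
        rows.append({"characteristic": label, **cells, "p": p})

    out = pd.DataFrame(rows)
    for g in genders:
        out = out.rename(columns={g: f"{g} (n={len(sub[g])})"})
    return out
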