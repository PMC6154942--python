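"""Economic-status, lifestyle and additive-risk stratification.

Covers the population-level risk analyses: MetS prevalence across spending
groups with pairwise chi-square tests, Spearman correlations of lifestyle
variables with spending, and the 16-cell grid crossing MetS-index quartiles
with sedentary-time quartiles to expose the additive effect of dysbiosis and
a sedentary lifestyle on MetS prevalence.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import bh_adjust, chi_square, spearman

__all__ = [
    "quartilize",
    "prevalence_by_group",
    "lifestyle_correlations",
    "GridResult",
    "additive_risk_grid",
]

DEFAULT_LIFESTYLE = ("sedentary", "diet_veg", "diet_fruit", "diet_grain", "diet_meat", "smoking")


def quartilize(values) -> np.ndarray:
    """Quartile labels 1..4 cut at the 25/50/75 empirical percentiles.

    Percentiles use midpoint interpolation; ties at a cut point go to the
    lower quartile. Labels are invariant under strictly monotone transforms
    of the values.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("need at least 4 values to quartilize")
    cuts = np.percentile(v, [25, 50, 75], method="midpoint")
    if cuts[0] == cuts[2]:
        raise ValueError("degenerate input: quartile cut points coincide")
    return 1 + (v[:, None] > cuts[None, :]).sum(axis=1)


def prevalence_by_group(cohort: pd.DataFrame, groups) -> pd.DataFrame:
    """Per-group MetS prevalence with BH-adjusted pairwise chi-square tests.

    Returns one row per group (n, n_mets, prevalence %) plus, attached as
    ``result.attrs['pairwise']``, the long-form pairwise q-value table.
    """
    groups = pd.Series(np.asarray(groups), index=cohort.index, name="group")
    mets = cohort["mets"].astype(bool)
    rows = []
    for level, idx in groups.groupby(groups).groups.items():
        n = len(idx)
        if n == 0:
            warnings.warn(f"empty group {level!r} excluded", stacklevel=2)
            continue
        k = int(mets.loc[idx].sum())
        rows.append(
            {"group": level, "n": n, "n_mets": k, "prevalence_pct": 100.0 * k / n}
        )
    out = pd.DataFrame(rows).set_index("group")
    pairs = []
    levels = list(out.index)
    for g1, g2 in itertools.combinations(levels, 2):
        k1, n1 = out.loc[g1, "n_mets"], out.loc[g1, "n"]
        k2, n2 = out.loc[g2, "n_mets"], out.loc[g2, "n"]
        table = [[k1, n1 - k1], [k2, n2 - k2]]
        try:
            res = chi_square(table)
            pairs.append({"group1": g1, "group2": g2, "statistic": res.statistic, "p": res.p})
        except ValueError:
            pairs.append({"group1": g1, "group2": g2, "statistic": np.nan, "p": np.nan})
    pairwise = pd.DataFrame(pairs)
    if len(pairwise):
        tested = pairwise["p"].notna()
        pairwise["q"] = np.nan
        if tested.any():
            pairwise.loc[tested, "q"] = bh_adjust(pairwise.loc[tested, "p"].to_numpy())
    out.attrs["pairwise"] = pairwise
    return out


def lifestyle_correlations(
    cohort: pd.DataFrame, target: str = "spending", variables=DEFAULT_LIFESTYLE
) -> pd.DataFrame:
    """Spearman correlation of each lifestyle variable with ``target``.

    Constant columns are skipped with a warning; BH across tested variables.
    """
    rows = []
    for var in variables:
        if var not in cohort.columns:
            warnings.warn(f"variable {var!r} missing, skipped", stacklevel=2)
            continue
        x = cohort[var].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            warnings.warn(f"variable {var!r} constant, skipped", stacklevel=2)
            continue
        rho, p = spearman(x, cohort[target].to_numpy(dtype=float))
        rows.append({"variable": var, "rho": rho, "p": p})
    out = pd.DataFrame(rows).set_index("variable")
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
        out["sign"] = np.sign(out["rho"]).astype(int)
    return out


@dataclass
class GridResult:
    """4x4 (index quartile x sedentary quartile) MetS-prevalence grid.

    ``cells`` has one row per cell (n, n_mets, prevalence %); ``pairwise``
    holds BH-adjusted chi-square tests between all cell pairs; ``occupancy``
    maps each spending level to the percentage of that level's population in
    every cell.
    """

    cells: pd.DataFrame
    pairwise: pd.DataFrame
    occupancy: dict = field(default_factory=dict)

    def prevalence_matrix(self) -> pd.DataFrame:
        return self.cells.reset_index().pivot(
            index="sedentary_q", columns="index_q", values="prevalence_pct"
        )

    def corner_contrast(self) -> dict:
        """Prevalences of the four corner patterns of the additive story."""
        p = self.cells["prevalence_pct"]
        return {
            "high_index_high_sedentary": float(p.get((4, 4), np.nan)),
            "high_index_low_sedentary": float(p.get((4, 1), np.nan)),
            "low_index_high_sedentary": float(p.get((1, 4), np.nan)),
            "low_index_low_sedentary": float(p.get((1, 1), np.nan)),
        }


def additive_risk_grid(
    index: pd.Series,
    cohort: pd.DataFrame,
    spending_groups: str | None = "spending_group",
) -> GridResult:
    """Cross MetS-index and sedentary-time quartiles into a 16-cell grid.

    Cells are keyed (index_q, sedentary_q). Empty cells are reported with
    undefined prevalence and excluded from the pairwise tests.
    """
    cohort = cohort.loc[index.index]
    iq = quartilize(index.to_numpy())
    sq = quartilize(cohort["sedentary"].to_numpy())
    mets = cohort["mets"].astype(bool).to_numpy()

    rows = []
    for qi in (1, 2, 3, 4):
        for qs in (1, 2, 3, 4):
            mask = (iq == qi) & (sq == qs)
            n = int(mask.sum())
            k = int(mets[mask].sum())
            rows.append(
                {
                    "index_q": qi,
                    "sedentary_q": qs,
                    "n": n,
                    "n_mets": k,
                    "prevalence_pct": 100.0 * k / n if n else np.nan,
                }
            )
    cells = pd.DataFrame(rows).set_index(["index_q", "sedentary_q"])

    keys = [key for key in cells.index if cells.loc[key, "n"] > 0]
    pairs = []
    for c1, c2 in itertools.combinations(keys, 2):
        k1, n1 = cells.loc[c1, "n_mets"], cells.loc[c1, "n"]
        k2, n2 = cells.loc[c2, "n_mets"], cells.loc[c2, "n"]
        table = [[k1, n1 - k1], [k2, n2 - k2]]
        try:
            res = chi_square(table)
            stat, p = res.statistic, res.p
        except ValueError:  # a zero marginal (e.g. no MetS in either cell)
            stat, p = np.nan, np.nan
        pairs.append({"cell1": c1, "cell2": c2, "statistic": stat, "p": p})
    pairwise = pd.DataFrame(pairs)
    if len(pairwise):
        tested = pairwise["p"].notna()
        pairwise["q"] = np.nan
        if tested.any():
            pairwise.loc[tested, "q"] = bh_adjust(pairwise.loc[tested, "p"].to_numpy())

    occupancy: dict = {}
    if spending_groups is not None and spending_groups in cohort.columns:
        for level, sub in cohort.groupby(spending_groups, observed=True):
            sel = cohort.index.get_indexer(sub.index)
            grid = np.zeros((4, 4))
            for qi in (1, 2, 3, 4):
                for qs in (1, 2, 3, 4):
                    grid[qi - 1, qs - 1] = ((iq[sel] == qi) & (sq[sel] == qs)).sum()
            occupancy[level] = pd.DataFrame(
                100.0 * grid / grid.sum(),
                index=pd.Index([1, 2, 3, 4], name="index_q"),
                columns=pd.Index([1, 2, 3, 4], name="sedentary_q"),
            )
    return GridResult(cells=cells, pairwise=pairwise, occupancy=occupancy)
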