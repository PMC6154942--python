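"""The gut microbial MetS index: a per-sample dysbiosis score.

The index accumulates the relative abundances of OTUs significantly
associated with MetS or its diagnostic factors, each weighted by its
association coefficient and significance:

    w_i = sign(beta_i) * |beta_i| * (-log10 q_i),   summed over factors,
    I_s = sum_i r_si * w_i,                         then z-standardised.

HDL coefficients enter with flipped sign (low HDL is the disorder). OTUs
significant for several factors contribute once, with their weights summed.
The exact weighting is one documented choice among close variants; the
``weight_mode`` parameter switches to |beta|-only or -log10(q)-only weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import AssociationRecord, OtuTable
from .stats import bh_adjust, spearman, wilcoxon_rank_sum

__all__ = [
    "MetsIndexScorer",
    "compute_mets_index",
    "stratified_validation",
    "index_vs_economics",
]

#: factors whose significant associations feed the index
DEFAULT_INDEX_FACTORS = ("mets", "waist", "sbp", "dbp", "tg", "hdl", "fbg")


class MetsIndexScorer(BaseEstimator, TransformerMixin):
    """Score samples by MetS-associated dysbiosis.

    ``fit`` consumes association records (significant ones for the factors in
    ``factor_set``) and builds per-OTU weights; ``transform`` maps an OTU
    table to the standardised per-sample index.
    """

    def __init__(
        self,
        factor_set=DEFAULT_INDEX_FACTORS,
        weight_mode: str = "beta_logq",
        standardize: bool = True,
    ):
        self.factor_set = factor_set
        self.weight_mode = weight_mode
        self.standardize = standardize

    def fit(self, records, y=None):
        if self.weight_mode not in ("beta_logq", "beta", "logq"):
            raise ValueError("weight_mode must be 'beta_logq', 'beta' or 'logq'")
        weights: dict[str, float] = {}
        wanted = set(self.factor_set)
        for rec in records:
            if not rec.significant or rec.factor not in wanted:
                continue
            sign = -rec.direction if rec.factor == "hdl" else rec.direction
            logq = -np.log10(max(rec.q, np.finfo(float).tiny))
            if self.weight_mode == "beta_logq":
                w = sign * abs(rec.beta) * logq
            elif self.weight_mode == "beta":
                w = sign * abs(rec.beta)
            else:
                w = sign * logq
            weights[rec.otu_id] = weights.get(rec.otu_id, 0.0) + w
        if not weights:
            raise ValueError("no significant MetS-associated records: empty index")
        self.weights_ = pd.Series(weights, name="weight").sort_index()
        return self

    def transform(self, table: OtuTable) -> pd.Series:
        rel = table.relative_abundance()
        common = [o for o in self.weights_.index if o in rel.columns]
        raw = rel[common].to_numpy() @ self.weights_.loc[common].to_numpy()
        idx = pd.Series(raw, index=rel.index, name="mets_index")
        if self.standardize:
            sd = idx.std(ddof=0)
            if sd > 0:
                idx = (idx - idx.mean()) / sd
        return idx


def compute_mets_index(
    table: OtuTable,
    records,
    factor_set=DEFAULT_INDEX_FACTORS,
    weight_mode: str = "beta_logq",
    standardize: bool = True,
) -> pd.Series:
    """Fit the scorer on ``records`` and score ``table`` in one call."""
    scorer = MetsIndexScorer(
        factor_set=factor_set, weight_mode=weight_mode, standardize=standardize
    )
    return scorer.fit(records).transform(table)


def stratified_validation(
    index: pd.Series, cohort: pd.DataFrame, strata: str
) -> pd.DataFrame:
    """Wilcoxon MetS vs non-MetS comparison of the index within each stratum.

    Strata with a single MetS class are skipped (reported with NaN p).
    p-values are BH-adjusted across the tested strata.
    """
    if strata not in cohort.columns:
        raise ValueError(f"stratum variable {strata!r} not in cohort")
    cohort = cohort.loc[index.index]
    rows = []
    for level, sub in cohort.groupby(strata, observed=True):
        mets = index.loc[sub.index[sub["mets"]]]
        non = index.loc[sub.index[~sub["mets"]]]
        row = {
            "stratum": level,
            "n_mets": len(mets),
            "n_non": len(non),
            "median_mets": float(np.median(mets)) if len(mets) else np.nan,
            "median_non": float(np.median(non)) if len(non) else np.nan,
        }
        if len(mets) and len(non):
            res = wilcoxon_rank_sum(mets.to_numpy(), non.to_numpy())
            row.update(statistic=res.statistic, p=res.p, skipped=False)
        else:
            row.update(statistic=np.nan, p=np.nan, skipped=True)
        rows.append(row)
    out = pd.DataFrame(rows).set_index("stratum")
    tested = out.index[~out["skipped"]]
    out["q"] = np.nan
    if len(tested):
        out.loc[tested, "q"] = bh_adjust(out.loc[tested, "p"].to_numpy())
    return out


def index_vs_economics(
    index: pd.Series,
    cohort: pd.DataFrame,
    subset: str = "non_mets",
    variable: str = "spending",
) -> tuple[float, float]:
    """Spearman correlation of the index with an economic variable.

    ``subset`` restricts to ``'mets'``, ``'non_mets'`` or ``'all'`` samples.
    """
    cohort = cohort.loc[index.index]
    if subset == "mets":
        keep = cohort["mets"]
    elif subset == "non_mets":
        keep = ~cohort["mets"]
    elif subset == "all":
        keep = pd.Series(True, index=cohort.index)
    else:
        raise ValueError("subset must be 'mets', 'non_mets' or 'all'")
    sel = cohort.index[keep]
    if len(sel) < 3:
        raise ValueError("subset smaller than 3 samples")
    return spearman(index.loc[sel].to_numpy(), cohort.loc[sel, variable].to_numpy())
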