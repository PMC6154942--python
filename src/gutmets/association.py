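"""Confounder-adjusted per-OTU association modelling and network summaries.

The engine follows the multivariate-association-with-linear-models recipe
(MaAsLin): arcsine-square-root transformed relative abundances are regressed,
one OTU and one host factor at a time, on the factor plus a fixed confounder
set (age, gender, Bristol stool scale, geographic region by default);
coefficients, two-sided p-values and Benjamini-Hochberg q-values are
reported per factor family. An optional componentwise-boosting screen can
drop never-selected covariates before the final least-squares fit.

Estimators follow scikit-learn conventions (``fit``, ``transform``,
``get_params``; fitted attributes end in an underscore) and compose with
sklearn pipelines where the matrix types allow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps
from sklearn.base import BaseEstimator, TransformerMixin

from .io import FACTOR_ORDER, AssociationRecord, OtuTable, TaxonomyLabel
from .simulate import factor_matrix
from .stats import bh_adjust

__all__ = [
    "PrevalenceFilter",
    "prevalence_filter",
    "ArcsineSqrtTransform",
    "transform_abundance",
    "AssociationModel",
    "fit_associations",
    "NetworkSummary",
    "summarize_network",
]

DEFAULT_CONFOUNDERS = ("age", "gender", "region", "bristol")
DEFAULT_FACTORS = ("waist", "sbp", "dbp", "tg", "hdl", "fbg", "mets")


class PrevalenceFilter(BaseEstimator, TransformerMixin):
    """Keep OTUs detected in at least ``min_prevalence`` of samples.

    The boundary is inclusive: an OTU present in exactly the threshold
    fraction is kept (presence in >= ceil(min_prevalence * n) samples).
    """

    def __init__(self, min_prevalence: float = 0.10):
        self.min_prevalence = min_prevalence

    def fit(self, table: OtuTable, y=None):
        if not (0.0 < self.min_prevalence <= 1.0):
            raise ValueError("min_prevalence must lie in (0, 1]")
        counts = table.counts
        needed = int(np.ceil(self.min_prevalence * counts.shape[0]))
        present = (counts > 0).sum(axis=0)
        self.kept_otus_ = list(counts.columns[present >= needed])
        self.n_samples_ = counts.shape[0]
        if not self.kept_otus_:
            raise ValueError("prevalence filter removed every OTU")
        return self

    def transform(self, table: OtuTable) -> OtuTable:
        return table.select_otus(self.kept_otus_)


def prevalence_filter(table: OtuTable, min_prevalence: float = 0.10) -> OtuTable:
    return PrevalenceFilter(min_prevalence).fit(table).transform(table)


class ArcsineSqrtTransform(BaseEstimator, TransformerMixin):
    """Variance-stabilising transform y = arcsin(sqrt(relative abundance)).

    Values lie in [0, pi/2]; zeros map to zero. ``mode='log10'`` switches to
    log10 of the pseudo-counted relative abundance instead.
    """

    def __init__(self, mode: str = "arcsin", pseudo: float = 0.5):
        self.mode = mode
        self.pseudo = pseudo

    def fit(self, table, y=None):
        if self.mode not in ("arcsin", "log10"):
            raise ValueError("mode must be 'arcsin' or 'log10'")
        return self

    def transform(self, table) -> pd.DataFrame:
        if isinstance(table, OtuTable):
            depth = table.counts.sum(axis=1).to_numpy()[:, None]
            counts = table.counts
        else:
            counts = pd.DataFrame(table)
            depth = counts.sum(axis=1).to_numpy()[:, None]
        rel = counts.to_numpy(dtype=float) / depth
        if self.mode == "arcsin":
            out = np.arcsin(np.sqrt(np.clip(rel, 0.0, 1.0)))
        else:
            out = np.log10((counts.to_numpy() + self.pseudo) / depth)
        return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def transform_abundance(table: OtuTable, mode: str = "arcsin") -> pd.DataFrame:
    return ArcsineSqrtTransform(mode=mode).fit(table).transform(table)


def _confounder_matrix(cohort: pd.DataFrame, confounders) -> pd.DataFrame:
    """Standardised / dummy-coded confounder columns."""
    cols = {}
    for name in confounders:
        if name == "gender":
            cols["gender_male"] = (cohort["gender"] == "male").astype(float)
        elif name == "region":
            dummies = pd.get_dummies(cohort["region"], prefix="region", drop_first=True)
            for c in dummies.columns:
                cols[c] = dummies[c].astype(float)
        else:
            if name not in cohort.columns:
                raise ValueError(f"confounder {name!r} not in cohort")
            v = cohort[name].to_numpy(dtype=float)
            sd = v.std()
            cols[name] = (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)
    return pd.DataFrame(cols, index=cohort.index)


def _boost_screen(
    X: np.ndarray, Y: np.ndarray, forced: int, n_iter: int = 100, step: float = 0.1
) -> np.ndarray:
    """Componentwise least-squares boosting screen.

    Returns a boolean (n_covariates, n_otus) selection mask; the forced
    (factor) column is always kept. Covariates never selected in ``n_iter``
    rounds are dropped from that OTU's final fit.
    """
    n, p = X.shape
    Xs = X - X.mean(axis=0)
    norms = (Xs**2).sum(axis=0)
    norms[norms == 0] = np.inf
    R = Y - Y.mean(axis=0)
    selected = np.zeros((p, Y.shape[1]), dtype=bool)
    selected[forced] = True
    for _ in range(n_iter):
        coef = Xs.T @ R / norms[:, None]  # least-squares coefficient per covariate
        gain = (coef**2) * norms[:, None]  # SS reduction
        best = np.argmax(gain, axis=0)
        cols = np.arange(Y.shape[1])
        selected[best, cols] = True
        R -= step * Xs[:, best] * coef[best, cols]
    return selected


def _ols_batch(X: np.ndarray, Y: np.ndarray, j: int) -> tuple[np.ndarray, np.ndarray]:
    """Coefficient j and its two-sided p for every column of Y at once."""
    n, p = X.shape
    xtx = X.T @ X
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError:
        xtx_inv = np.linalg.pinv(xtx)
    B = xtx_inv @ X.T @ Y
    resid = Y - X @ B
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[j, j], 0.0))
    beta = B[j]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    pvals = 2.0 * _sps.t.sf(np.abs(t), dof)
    return beta, np.clip(pvals, np.finfo(float).tiny, 1.0)


def _drop_aliased(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    """Drop columns until the design has full rank (warn per drop)."""
    while np.linalg.matrix_rank(X) < X.shape[1]:
        # drop the last column involved in the dependency
        for k in range(X.shape[1] - 1, 0, -1):
            reduced = np.delete(X, k, axis=1)
            if np.linalg.matrix_rank(reduced) == np.linalg.matrix_rank(X):
                warnings.warn(f"dropping aliased covariate {names[k]!r}", stacklevel=2)
                X = reduced
                names = names[:k] + names[k + 1 :]
                break
        else:  # pragma: no cover - defensive
            break
    return X, names


class AssociationModel(BaseEstimator):
    """Per-OTU, per-factor additive linear model with confounder adjustment.

    Parameters
    ----------
    factors
        Host variables to associate, one model per (OTU, factor).
    confounders
        Covariates forced into (or, with ``selection='boosted'``, offered to)
        every model. ``'gender'`` and ``'region'`` are dummy-coded, others
        standardised.
    selection
        ``'none'`` fits the full additive model; ``'boosted'`` first screens
        confounders per OTU by componentwise least-squares boosting (100
        iterations, step 0.1) and drops never-selected ones.
    fdr
        Benjamini-Hochberg threshold for flagging a record significant.
    bh_family
        ``'per_factor'`` adjusts across OTUs within each factor (default) or
        ``'global'`` across all (OTU, factor) pairs.

    Attributes
    ----------
    records_ : list of AssociationRecord
    significant_ : list of AssociationRecord with q <= fdr
    """

    def __init__(
        self,
        factors=DEFAULT_FACTORS,
        confounders=DEFAULT_CONFOUNDERS,
        selection: str = "none",
        fdr: float = 0.05,
        bh_family: str = "per_factor",
        transform: str = "arcsin",
    ):
        self.factors = factors
        self.confounders = confounders
        self.selection = selection
        self.fdr = fdr
        self.bh_family = bh_family
        self.transform = transform

    def fit(self, table: OtuTable, cohort: pd.DataFrame):
        if self.selection not in ("none", "boosted"):
            raise ValueError("selection must be 'none' or 'boosted'")
        if self.bh_family not in ("per_factor", "global"):
            raise ValueError("bh_family must be 'per_factor' or 'global'")
        for f in self.factors:
            if f not in FACTOR_ORDER:
                raise ValueError(f"unknown factor {f!r}")
        cohort = cohort.loc[table.counts.index]
        Y = (
            ArcsineSqrtTransform(mode=self.transform)
            .fit(table)
            .transform(table)
            .to_numpy()
        )
        n, m = Y.shape
        fmat = factor_matrix(cohort)
        conf = _confounder_matrix(cohort, self.confounders)
        otu_ids = table.otu_ids
        tax = table.taxonomy

        all_records: list[AssociationRecord] = []
        per_factor_rows: dict[str, list[dict]] = {}
        for factor in self.factors:
            names = ["intercept", factor] + list(conf.columns)
            X = np.column_stack([np.ones(n), fmat[factor].to_numpy(), conf.to_numpy()])
            X, names = _drop_aliased(X, names)
            n_covariates = X.shape[1] - 1
            if n < 10 + n_covariates:
                warnings.warn(
                    f"skipping factor {factor!r}: {n} samples < 10 + {n_covariates}",
                    stacklevel=2,
                )
                continue
            j = names.index(factor)
            if self.selection == "boosted" and X.shape[1] > 2:
                mask = _boost_screen(X[:, 1:], Y, forced=j - 1)
                beta = np.empty(m)
                pval = np.empty(m)
                # fit OTUs sharing a selection pattern together
                patterns = np.unique(mask.T, axis=0)
                for pat in patterns:
                    cols = np.flatnonzero((mask.T == pat).all(axis=1))
                    keep = np.concatenate([[0], 1 + np.flatnonzero(pat)])
                    jj = int(np.flatnonzero(keep == j)[0])
                    b, p = _ols_batch(X[:, keep], Y[:, cols], jj)
                    beta[cols] = b
                    pval[cols] = p
            else:
                beta, pval = _ols_batch(X, Y, j)
            rows = [
                {
                    "otu_id": otu_ids[i],
                    "factor": factor,
                    "beta": float(beta[i]),
                    "p": float(pval[i]),
                    "n_used": n,
                    "taxonomy": "" if tax is None else str(tax.iloc[i]),
                }
                for i in range(m)
            ]
            per_factor_rows[factor] = rows

        if self.bh_family == "per_factor":
            for factor, rows in per_factor_rows.items():
                qvals = bh_adjust([r["p"] for r in rows])
                for r, q in zip(rows, qvals):
                    r["q"] = float(q)
                    all_records.append(self._record(r))
        else:
            flat = [r for rows in per_factor_rows.values() for r in rows]
            qvals = bh_adjust([r["p"] for r in flat])
            for r, q in zip(flat, qvals):
                r["q"] = float(q)
                all_records.append(self._record(r))

        self.n_samples_ = n
        self.records_ = all_records
        self.significant_ = [r for r in all_records if r.significant]
        return self

    def _record(self, row: dict) -> AssociationRecord:
        q = max(row["q"], row["p"])
        return AssociationRecord(
            otu_id=row["otu_id"],
            factor=row["factor"],
            beta=row["beta"],
            p=row["p"],
            q=q,
            n_used=row["n_used"],
            taxonomy=row["taxonomy"],
            significant=q <= self.fdr,
        )


def fit_associations(
    table: OtuTable,
    cohort: pd.DataFrame,
    factors=DEFAULT_FACTORS,
    confounders=DEFAULT_CONFOUNDERS,
    selection: str = "none",
    fdr: float = 0.05,
) -> list[AssociationRecord]:
    """Fit the association model and return all records (see AssociationModel)."""
    model = AssociationModel(
        factors=factors, confounders=confounders, selection=selection, fdr=fdr
    )
    return model.fit(table, cohort).records_


# --------------------------------------------------------------------------
# directional network summarisation


@dataclass
class NetworkSummary:
    """Directional bookkeeping of significant associations.

    ``per_factor`` counts use the modelled coefficient sign. ``per_taxon``
    and the grand totals apply the HDL valence flip: low HDL being the
    disorder, a positive HDL coefficient counts as a negative (protective)
    association when aggregated with the other factors.
    """

    rank: str
    per_factor: pd.DataFrame
    per_taxon: pd.DataFrame
    n_total: int
    n_positive: int
    n_negative: int


def _taxon_at(label: str, rank: str) -> str:
    if not label:
        return "Unassigned"
    try:
        name = TaxonomyLabel.parse(label).at(rank)
    except Exception:
        return "Unassigned"
    return name if name else "Unassigned"


def summarize_network(
    records,
    taxonomy: pd.Series | None = None,
    rank: str = "phylum",
    significant_only: bool = True,
) -> NetworkSummary:
    """Count significant associations by factor and by taxon at ``rank``."""
    recs = [r for r in records if (r.significant or not significant_only)]
    factor_counts = {f: [0, 0] for f in FACTOR_ORDER}
    taxon_counts: dict[str, list[int]] = {}
    n_pos = n_neg = 0
    for r in recs:
        direction = r.direction
        factor_counts[r.factor][0 if direction < 0 else 1] += 1
        valence = -direction if r.factor == "hdl" else direction
        if valence > 0:
            n_pos += 1
        else:
            n_neg += 1
        label = r.taxonomy
        if taxonomy is not None:
            label = taxonomy.get(r.otu_id, label)
        taxon = _taxon_at(label, rank)
        cell = taxon_counts.setdefault(taxon, [0, 0])
        cell[0 if valence < 0 else 1] += 1

    per_factor = pd.DataFrame(
        {
            "n_negative": {f: c[0] for f, c in factor_counts.items()},
            "n_positive": {f: c[1] for f, c in factor_counts.items()},
        }
    ).loc[list(FACTOR_ORDER)]
    per_factor = per_factor[(per_factor.sum(axis=1) > 0)]
    per_taxon = pd.DataFrame(
        {
            "n_negative": {t: c[0] for t, c in taxon_counts.items()},
            "n_positive": {t: c[1] for t, c in taxon_counts.items()},
        }
    ).sort_index()
    if len(per_taxon):
        per_taxon["total"] = per_taxon["n_negative"] + per_taxon["n_positive"]
    else:
        per_taxon = pd.DataFrame(columns=["n_negative", "n_positive", "total"])
    return NetworkSummary(
        rank=rank,
        per_factor=per_factor,
        per_taxon=per_taxon,
        n_total=len(recs),
        n_positive=n_pos,
        n_negative=n_neg,
    )
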