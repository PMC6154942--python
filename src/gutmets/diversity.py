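"""Rarefaction, alpha diversity and Bray-Curtis dissimilarity.

Conventions follow the QIIME 1 toolchain this analysis emulates: Shannon in
bits (log base 2, switchable to nats), Faith's PD including the stem path to
the root ("PD whole tree"), rarefaction by subsampling without replacement
with under-depth samples dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio
from scipy.spatial.distance import pdist, squareform

from .io import OtuTable
from .stats import bh_adjust, wilcoxon_rank_sum

__all__ = [
    "rarefy",
    "RarefactionReport",
    "shannon",
    "faith_pd",
    "alpha_diversity_table",
    "bray_curtis",
    "DistanceMatrix",
    "diversity_comparison",
]


@dataclass
class RarefactionReport:
    depth: int
    kept: list
    dropped: list


def rarefy(
    table: OtuTable, depth: int, seed: int = 0, return_report: bool = False
):
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped and listed in
    the report. Draws use the multivariate hypergeometric distribution, i.e.
    exact subsampling of the observed reads.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    totals = table.counts.sum(axis=1)
    kept = totals.index[totals >= depth].tolist()
    dropped = totals.index[totals < depth].tolist()
    if not kept:
        raise ValueError("no sample reaches the rarefaction depth")
    rows = []
    for sid in kept:
        row = table.counts.loc[sid].to_numpy()
        if row.sum() == depth:
            rows.append(row)
        else:
            rows.append(rng.multivariate_hypergeometric(row, depth))
    counts = pd.DataFrame(
        np.asarray(rows), index=pd.Index(kept, name=table.counts.index.name),
        columns=table.counts.columns,
    )
    out = OtuTable(counts, table.taxonomy)
    if return_report:
        return out, RarefactionReport(depth=depth, kept=kept, dropped=dropped)
    return out


def shannon(counts, base: float = 2.0) -> float:
    """Shannon diversity H = -sum p_i log p_i over non-zero proportions."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("Shannon diversity undefined for an all-zero sample")
    p = counts[counts > 0] / total
    return float(-(p * (np.log(p) / np.log(base))).sum())


def faith_pd(counts, otu_ids, tree: skbio.TreeNode) -> float:
    """Faith's phylogenetic diversity, root-inclusive.

    Total branch length of the minimal subtree connecting the tree's root and
    every observed (non-zero) OTU tip, including the path from the subtree to
    the root ("PD whole tree" convention).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape[0] != len(otu_ids):
        raise ValueError("counts and otu_ids lengths differ")
    observed = [o for o, c in zip(otu_ids, counts) if c > 0]
    if not observed:
        return 0.0
    tips = {t.name: t for t in tree.tips()}
    edges = set()
    for name in observed:
        if name not in tips:
            raise ValueError(f"OTU {name!r} observed but absent from tree")
        node = tips[name]
        while node.parent is not None:
            if id(node) in edges:
                break
            edges.add(id(node))
            node = node.parent
    # sum in a fixed traversal order so the float result is reproducible
    return float(
        sum(n.length for n in tree.traverse(include_self=False) if id(n) in edges)
    )


def alpha_diversity_table(
    table: OtuTable, tree: skbio.TreeNode | None = None, base: float = 2.0
) -> pd.DataFrame:
    """Per-sample Shannon (and PD when a tree is given)."""
    out = pd.DataFrame(index=table.counts.index)
    mat = table.counts.to_numpy()
    out["shannon"] = [shannon(row, base=base) for row in mat]
    if tree is not None:
        ids = table.otu_ids
        out["pd"] = [faith_pd(row, ids, tree) for row in mat]
    return out


@dataclass
class DistanceMatrix:
    """Symmetric sample-by-sample dissimilarity with zero diagonal."""

    sample_ids: list
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if v.shape[0] != len(self.sample_ids):
            raise ValueError("sample_ids length must match matrix size")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.all(np.diag(v) == 0):
            raise ValueError("distance matrix diagonal must be zero")
        self.values = v

    def submatrix(self, idx: np.ndarray) -> "DistanceMatrix":
        ids = [self.sample_ids[i] for i in idx]
        return DistanceMatrix(ids, self.values[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


def bray_curtis(table: OtuTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity, BC = 1 - 2*sum(min)/(sum u + sum v)."""
    counts = table.counts.to_numpy(dtype=float)
    if counts.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if (counts.sum(axis=1) == 0).any():
        sid = table.counts.index[counts.sum(axis=1) == 0][0]
        raise ValueError(f"Bray-Curtis undefined for zero-sum sample {sid!r}")
    dm = squareform(pdist(counts, metric="braycurtis"))
    np.fill_diagonal(dm, 0.0)
    return DistanceMatrix(table.sample_ids, dm)


def diversity_comparison(
    alpha: pd.DataFrame, groups: pd.Series
) -> pd.DataFrame:
    """Two-group Wilcoxon comparison of each alpha metric, BH across metrics."""
    groups = groups.reindex(alpha.index)
    levels = sorted(groups.dropna().unique())
    if len(levels) != 2:
        raise ValueError("diversity_comparison requires exactly two groups")
    rows = []
    for col in alpha.columns:
        x = alpha.loc[groups == levels[0], col].to_numpy()
        y = alpha.loc[groups == levels[1], col].to_numpy()
        res = wilcoxon_rank_sum(x, y)
        rows.append(
            {
                "metric": col,
                f"median_{levels[0]}": float(np.median(x)),
                f"median_{levels[1]}": float(np.median(y)),
                "statistic": res.statistic,
                "p": res.p,
            }
        )
    out = pd.DataFrame(rows).set_index("metric")
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out
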