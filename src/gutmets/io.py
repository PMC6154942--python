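"""Readers and writers for the tab-separated formats the pipeline touches.

Two OTU-table dialects are understood: the native dialect written by this
package (first header cell ``otu_id``, OTUs as rows, samples as columns, a
trailing ``taxonomy`` column) and the classic dense BIOM-style TSV (first
header cell ``#OTU ID``). Orientation is normalised internally to samples x
OTUs. Readers validate and reject rather than coerce; writers are
deterministic (fixed column order, floats at six significant digits).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import skbio

__all__ = [
    "OtuTable",
    "TaxonomyLabel",
    "FormatError",
    "read_otu_table",
    "write_otu_table",
    "read_newick",
    "write_newick",
    "AssociationRecord",
    "write_associations",
    "read_associations",
    "read_cohort",
    "write_cohort",
]

RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")
RANK_NAMES = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

#: canonical ordering of association factors in files and summaries
FACTOR_ORDER = ("waist", "sbp", "dbp", "tg", "hdl", "fbg", "mets", "income", "spending")


class FormatError(ValueError):
    """Malformed input file."""


@dataclass(frozen=True)
class TaxonomyLabel:
    """Seven-rank Greengenes-style taxonomy string, kingdom through species."""

    ranks: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ranks) != 7:
            raise ValueError("taxonomy requires exactly 7 ranks")

    @classmethod
    def parse(cls, label: str) -> "TaxonomyLabel":
        parts = [p.strip() for p in label.split(";")]
        if len(parts) != 7:
            raise FormatError(f"taxonomy {label!r} does not have 7 ranks")
        ranks = []
        for part, prefix in zip(parts, RANK_PREFIXES):
            if not part.startswith(prefix):
                raise FormatError(f"rank {part!r} missing prefix {prefix!r}")
            ranks.append(part[len(prefix) :])
        return cls(tuple(ranks))

    def at(self, rank: str) -> str:
        return self.ranks[RANK_NAMES.index(rank)]

    def __str__(self) -> str:
        return ";".join(p + r for p, r in zip(RANK_PREFIXES, self.ranks))


class OtuTable:
    """Sample x OTU count matrix with per-OTU taxonomy.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers, samples as index, OTU ids as
        columns.
    taxonomy
        Series of 7-rank taxonomy strings indexed by OTU id (optional).
    """

    def __init__(self, counts: pd.DataFrame, taxonomy: pd.Series | None = None):
        if counts.index.has_duplicates:
            raise FormatError("duplicate sample ids")
        if counts.columns.has_duplicates:
            raise FormatError("duplicate OTU ids")
        values = counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.equal(np.mod(values, 1), 0)):
                bad = np.argwhere(np.mod(values, 1) != 0)[0]
                raise FormatError(
                    f"non-integer count at sample {counts.index[bad[0]]!r}, "
                    f"OTU {counts.columns[bad[1]]!r}"
                )
            counts = counts.astype(np.int64)
            values = counts.to_numpy()
        if (values < 0).any():
            bad = np.argwhere(values < 0)[0]
            raise FormatError(
                f"negative count at sample {counts.index[bad[0]]!r}, "
                f"OTU {counts.columns[bad[1]]!r}"
            )
        if taxonomy is not None:
            taxonomy = taxonomy.reindex(counts.columns)
            if taxonomy.isna().any():
                missing = taxonomy.index[taxonomy.isna()][0]
                raise FormatError(f"missing taxonomy for OTU {missing!r}")
        self.counts = counts
        self.taxonomy = taxonomy

    # -- basic API -----------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def sample_sums(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=1)
        if (totals == 0).any():
            raise ValueError("zero-sum sample has no relative abundance")
        return self.counts.div(totals, axis=0)

    def select_otus(self, otu_ids: Sequence[str]) -> "OtuTable":
        tax = self.taxonomy.loc[list(otu_ids)] if self.taxonomy is not None else None
        return OtuTable(self.counts.loc[:, list(otu_ids)], tax)

    def select_samples(self, sample_ids: Sequence[str]) -> "OtuTable":
        return OtuTable(self.counts.loc[list(sample_ids)], self.taxonomy)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        same_counts = self.counts.equals(other.counts)
        if self.taxonomy is None or other.taxonomy is None:
            return same_counts and (self.taxonomy is None) == (other.taxonomy is None)
        return same_counts and self.taxonomy.equals(other.taxonomy)


def write_otu_table(table: OtuTable, path) -> None:
    """Native dialect: OTUs x samples, trailing taxonomy column."""
    out = table.counts.T.copy()
    out.index.name = "otu_id"
    if table.taxonomy is not None:
        out["taxonomy"] = table.taxonomy
    out.to_csv(path, sep="\t")


def read_otu_table(path) -> OtuTable:
    """Read either dialect; orientation normalised to samples x OTUs."""
    path = Path(path)
    skip = 0
    with open(path) as fh:
        header = fh.readline()
        # BIOM convention sometimes precedes the header with a comment line
        if header.startswith("# Constructed"):
            header = fh.readline()
            skip = 1
        toks = header.rstrip("\n").split("\t")
        first_tok = toks[0]
    # pandas mangles duplicate header names, so check the raw header
    if len(set(toks[1:])) != len(toks) - 1:
        raise FormatError("duplicate column ids in header")
    if first_tok in ("#OTU ID", "otu_id"):
        df = pd.read_csv(path, sep="\t", index_col=0, skiprows=skip)
        tax = None
        if "taxonomy" in df.columns:
            tax = df.pop("taxonomy").astype(str)
        if df.index.has_duplicates:
            raise FormatError("duplicate OTU ids")
        if df.columns.has_duplicates:
            raise FormatError("duplicate sample ids")
        _check_numeric(df)
        counts = df.T
        counts.index.name = "sample_id"
        counts.columns.name = None
        if tax is not None:
            for label in tax:
                TaxonomyLabel.parse(label)
        return OtuTable(counts, tax)
    if first_tok == "sample_id":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.index.has_duplicates:
            raise FormatError("duplicate sample ids")
        if df.columns.has_duplicates:
            raise FormatError("duplicate OTU ids")
        _check_numeric(df)
        df.columns.name = None
        return OtuTable(df)
    raise FormatError(
        f"unrecognised OTU-table header token {first_tok!r}; "
        "expected '#OTU ID', 'otu_id' or 'sample_id'"
    )


def _check_numeric(df: pd.DataFrame) -> None:
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = df.index[vals.isna()][0]
            raise FormatError(f"non-numeric count at row {row!r}, column {col!r}")
        df[col] = vals


def read_newick(path_or_str) -> skbio.TreeNode:
    """Read a single rooted Newick tree; every edge must carry a length."""
    import io as _io

    src = path_or_str
    if isinstance(src, str) and src.lstrip().startswith("("):
        src = _io.StringIO(src)
    else:
        src = str(src)
    try:
        tree = skbio.TreeNode.read(src, format="newick")
    except Exception as exc:  # skbio raises several parser error types
        raise FormatError(f"could not parse Newick input: {exc}") from exc
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        raise FormatError("duplicate tip names in tree")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise FormatError(f"missing branch length on node {node.name!r}")
    return tree


def write_newick(tree: skbio.TreeNode, path) -> None:
    tree.write(str(path), format="newick")


@dataclass(frozen=True)
class AssociationRecord:
    """One OTU–factor association from the linear-model stage."""

    otu_id: str
    factor: str
    beta: float
    p: float
    q: float
    n_used: int
    taxonomy: str = ""
    significant: bool = False

    def __post_init__(self) -> None:
        if self.factor not in FACTOR_ORDER:
            raise ValueError(f"unknown factor {self.factor!r}")
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"p-value {self.p} outside (0, 1]")
        if self.q < self.p - 1e-12:
            raise ValueError("q must be >= p")

    @property
    def direction(self) -> int:
        return 1 if self.beta >= 0 else -1


def _fmt6(x: float) -> str:
    return f"{float(x):.6g}"


def write_associations(records: Iterable[AssociationRecord], path) -> None:
    """TSV of association records, stably sorted by (factor, q)."""
    records = list(records)
    for rec in records:
        if not np.isfinite(rec.beta):
            raise ValueError(f"refusing to write non-finite beta for {rec.otu_id}/{rec.factor}")
    order = {f: i for i, f in enumerate(FACTOR_ORDER)}
    records.sort(key=lambda r: (order[r.factor], r.q, r.otu_id))
    with open(path, "w") as fh:
        fh.write("otu_id\ttaxonomy\tfactor\tbeta\tp\tq\tn_used\tdirection\tsignificant\n")
        for r in records:
            fh.write(
                f"{r.otu_id}\t{r.taxonomy}\t{r.factor}\t{_fmt6(r.beta)}\t"
                f"{_fmt6(r.p)}\t{_fmt6(r.q)}\t{r.n_used}\t{r.direction:+d}\t"
                f"{int(r.significant)}\n"
            )


def read_associations(path) -> list[AssociationRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"otu_id": str, "taxonomy": str})
    df["taxonomy"] = df["taxonomy"].fillna("")
    return [
        AssociationRecord(
            otu_id=row.otu_id,
            factor=row.factor,
            beta=float(row.beta),
            p=float(row.p),
            q=float(row.q),
            n_used=int(row.n_used),
            taxonomy=row.taxonomy,
            significant=bool(row.significant),
        )
        for row in df.itertuples()
    ]


def write_cohort(cohort: pd.DataFrame, path) -> None:
    out = cohort.copy()
    if out.index.name == "sample_id":
        out = out.reset_index()
    if "sample_id" not in out.columns:
        raise ValueError("cohort table requires a sample_id column or index")
    cols = ["sample_id"] + [c for c in out.columns if c != "sample_id"]
    out[cols].to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise FormatError("cohort table missing sample_id column")
    if df["sample_id"].duplicated().any():
        raise FormatError("duplicate sample ids in cohort table")
    return df.set_index("sample_id")
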