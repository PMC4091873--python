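"""Tabular containers and I/O for count data, taxonomy and pathway membership.

All on-disk formats are plain TSV with a header row. Count tables are dense:
features absent from a sample are explicit zeros, never missing values.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Taxonomic ranks from most to least specific, plus the functional level.
RANKS = ("species", "genus", "family", "order", "class", "phylum", "superkingdom")
LEVELS = RANKS + ("ortholog_group",)


class TableFormatError(ValueError):
    """Raised when an input table violates the expected TSV dialect."""


@dataclass
class CountTable:
    """Feature-by-sample matrix of non-negative integer counts.

    Parameters
    ----------
    counts : pandas.DataFrame
        Integer matrix, features on rows, samples on columns.
    level : str
        One of :data:`LEVELS` — the taxonomic rank or ``ortholog_group``.
    annotated_total : pandas.Series, optional
        Per-sample denominator of annotated reads. Defaults to the column
        sums; carried separately because normalisation may use the number
        of reads annotated at the level rather than the level's column sum.
    """

    counts: pd.DataFrame
    level: str
    annotated_total: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}; expected one of {LEVELS}")
        c = self.counts
        c.index.name = None
        c.columns.name = None
        if c.index.has_duplicates:
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise TableFormatError(f"duplicate feature ids: {dups}")
        if c.columns.has_duplicates:
            raise TableFormatError("duplicate sample ids")
        arr = c.to_numpy()
        if arr.size == 0:
            raise TableFormatError("empty count table")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise TableFormatError("counts must be integral")
            self.counts = c = c.round().astype(np.int64)
            arr = c.to_numpy()
        if (arr < 0).any():
            raise TableFormatError("counts must be non-negative")
        colsum = c.sum(axis=0)
        if self.annotated_total is None:
            self.annotated_total = colsum.astype(np.int64)
        else:
            tot = pd.Series(self.annotated_total).reindex(c.columns)
            if tot.isna().any():
                raise TableFormatError("annotated_total missing for some samples")
            if (tot <= 0).any():
                raise TableFormatError("annotated_total must be positive")
            if (colsum > tot).any():
                raise TableFormatError("column sums exceed annotated_total")
            self.annotated_total = tot.astype(np.int64)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def write(self, path: str | Path) -> None:
        """Write counts plus a trailing ``#annotated_total`` row."""
        df = self.counts.copy()
        df.index.name = self.level
        with open(path, "w", encoding="utf-8") as fh:
            df.to_csv(fh, sep="\t")
            fh.write(
                "#annotated_total\t"
                + "\t".join(str(int(v)) for v in self.annotated_total)
                + "\n"
            )


@dataclass
class RelativeAbundanceTable:
    """Same shape as :class:`CountTable` with real values in [0, 1]."""

    values: pd.DataFrame
    level: str

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        if (arr < 0).any() or (arr > 1 + 1e-12).any():
            raise ValueError("relative abundances must lie in [0, 1]")
        sums = arr.sum(axis=0)
        if (sums > 1 + 1e-9).any():
            raise ValueError("per-sample relative abundances must sum to <= 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def write(self, path: str | Path) -> None:
        df = self.values.copy()
        df.index.name = self.level
        df.to_csv(path, sep="\t")


@dataclass
class TaxonomyMap:
    """species_id -> one parent name per rank above species."""

    table: pd.DataFrame  # index species_id, columns genus..superkingdom

    PARENT_RANKS = RANKS[1:]

    def __post_init__(self) -> None:
        missing = [r for r in self.PARENT_RANKS if r not in self.table.columns]
        if missing:
            raise TableFormatError(f"taxonomy map missing rank columns: {missing}")
        if self.table.index.has_duplicates:
            raise TableFormatError("taxonomy map has duplicate species ids")
        sub = self.table[list(self.PARENT_RANKS)]
        if sub.isna().any().any() or (sub == "").any().any():
            raise TableFormatError("taxonomy map has empty rank entries")

    def parent(self, rank: str) -> pd.Series:
        if rank == "species":
            return pd.Series(self.table.index, index=self.table.index)
        if rank not in self.PARENT_RANKS:
            raise ValueError(f"unknown rank {rank!r}")
        return self.table[rank]

    def write(self, path: str | Path) -> None:
        df = self.table[list(self.PARENT_RANKS)].copy()
        df.index.name = "species"
        df.to_csv(path, sep="\t")


@dataclass
class PathwayMembership:
    """Many-to-many ortholog-group/pathway pairs plus reference pathway sizes.

    ``database_size[p]`` is the total number of enzyme functions in the
    reference pathway, an upper bound on the membership observed here.
    """

    pairs: pd.DataFrame  # columns: ortholog_group, pathway
    database_size: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        need = {"ortholog_group", "pathway"}
        if not need.issubset(self.pairs.columns):
            raise TableFormatError("membership needs ortholog_group and pathway columns")
        self.pairs = self.pairs.drop_duplicates().reset_index(drop=True)
        realized = self.pairs.groupby("pathway")["ortholog_group"].nunique()
        for pw, n in realized.items():
            size = self.database_size.get(pw)
            if size is None:
                self.database_size[pw] = int(n)
            elif size < n:
                raise TableFormatError(
                    f"pathway {pw}: database size {size} < observed membership {n}"
                )

    @property
    def pathways(self) -> list[str]:
        return sorted(self.pairs["pathway"].unique())

    def members(self, pathway: str) -> set[str]:
        sel = self.pairs.loc[self.pairs["pathway"] == pathway, "ortholog_group"]
        return set(sel)

    def as_dict(self) -> dict[str, set[str]]:
        return {
            pw: set(grp["ortholog_group"])
            for pw, grp in self.pairs.groupby("pathway")
        }

    def write(self, pairs_path: str | Path, sizes_path: str | Path) -> None:
        self.pairs.sort_values(["pathway", "ortholog_group"]).to_csv(
            pairs_path, sep="\t", index=False
        )
        sizes = pd.DataFrame(
            sorted(self.database_size.items()), columns=["pathway", "database_size"]
        )
        sizes.to_csv(sizes_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# readers


def read_count_table(
    path: str | Path,
    level: str,
    annotated_total: Mapping[str, int] | None = None,
) -> CountTable:
    """Read a TSV count table (feature id in column 1, samples in the rest).

    A trailing ``#annotated_total`` row, if present, supplies the per-sample
    denominators; otherwise the ``annotated_total`` argument or the column
    sums are used.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if not text.strip():
        raise TableFormatError(f"{path}: empty file")
    lines = text.splitlines()
    totals_row = None
    body = []
    for ln in lines:
        if ln.startswith("#annotated_total"):
            totals_row = ln.split("\t")[1:]
        elif ln.strip():
            body.append(ln)
    if len(body) < 2:
        raise TableFormatError(f"{path}: no data rows")
    df = pd.read_csv(io.StringIO("\n".join(body)), sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise TableFormatError(f"{path}: no sample columns")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise TableFormatError(f"{path}: non-numeric cells")
    if not np.allclose(arr, np.round(arr)):
        raise TableFormatError(f"{path}: non-integer counts")
    if (arr < 0).any():
        raise TableFormatError(f"{path}: negative counts")
    df = df.round().astype(np.int64)
    df.index = df.index.astype(str)
    df.index.name = None
    tot: pd.Series | None = None
    if totals_row is not None:
        if len(totals_row) != df.shape[1]:
            raise TableFormatError(f"{path}: annotated_total row length mismatch")
        tot = pd.Series([int(v) for v in totals_row], index=df.columns)
    elif annotated_total is not None:
        tot = pd.Series(dict(annotated_total))
    return CountTable(counts=df, level=level, annotated_total=tot)


def read_taxonomy_map(path: str | Path) -> TaxonomyMap:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return TaxonomyMap(table=df)


def read_pathway_membership(
    pairs_path: str | Path, sizes_path: str | Path | None = None
) -> PathwayMembership:
    pairs = pd.read_csv(pairs_path, sep="\t", dtype=str)
    sizes: dict[str, int] = {}
    if sizes_path is not None:
        sz = pd.read_csv(sizes_path, sep="\t")
        sizes = dict(zip(sz.iloc[:, 0].astype(str), sz.iloc[:, 1].astype(int)))
    return PathwayMembership(pairs=pairs, database_size=sizes)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample metadata (sample_id, kitten, litter, diet, week)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "kitten": str, "litter": str, "diet": str})
    need = {"sample_id", "kitten", "litter", "diet", "week"}
    missing = need - set(df.columns)
    if missing:
        raise TableFormatError(f"metadata missing columns: {sorted(missing)}")
    return df.set_index("sample_id")


# ---------------------------------------------------------------------------
# transforms


def aggregate_to_rank(table: CountTable, taxonomy: TaxonomyMap, rank: str) -> CountTable:
    """Sum species-level counts within their parent taxon at ``rank``.

    Per-sample totals are conserved; aggregating to ``species`` is the
    identity.
    """
    if table.level != "species":
        raise ValueError("aggregation starts from a species-level table")
    if rank == "species":
        return table
    missing = [s for s in table.feature_ids if s not in taxonomy.table.index]
    if missing:
        raise KeyError(f"species missing from taxonomy map: {missing[:5]}")
    parents = taxonomy.parent(rank).reindex(table.feature_ids)
    agg = table.counts.groupby(parents.to_numpy()).sum()
    agg.index = agg.index.astype(str)
    agg = agg.sort_index()
    return CountTable(counts=agg, level=rank, annotated_total=table.annotated_total)


def to_relative_abundance(
    table: CountTable, denominator: str = "column_sum"
) -> RelativeAbundanceTable:
    """Divide each sample's counts by a per-sample denominator.

    ``denominator`` is ``"column_sum"`` (columns then sum to exactly 1) or
    ``"annotated_total"`` (the level's annotated-read total, which may exceed
    the column sum).
    """
    if denominator == "column_sum":
        denom = table.counts.sum(axis=0)
    elif denominator == "annotated_total":
        denom = table.annotated_total
    else:
        raise ValueError("denominator must be 'column_sum' or 'annotated_total'")
    denom = pd.Series(denom).reindex(table.counts.columns)
    if (denom <= 0).any():
        bad = list(denom.index[denom <= 0])
        raise ZeroDivisionError(f"zero denominator for samples: {bad}")
    vals = table.counts.div(denom, axis=1)
    return RelativeAbundanceTable(values=vals, level=table.level)
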