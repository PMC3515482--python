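"""Readers and writers for the plain-text interchange formats of the pipeline.

Every stage communicates through ordinary files: GWAS summary statistics as
tab-delimited tables (``snp  chrom  pos  p``), gene models as BED4, gene-set
databases as GMT, pairwise linkage disequilibrium as a three-column r² table,
and study metadata as a two-column table.  Internally all genomic coordinates
are 1-based and inclusive, matching the SNP position convention of summary
statistics; BED's 0-based half-open intervals are converted at the boundary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

SUMMARY_COLUMNS = ("snp", "chrom", "pos", "p")
ENRICHMENT_COLUMNS = (
    "category",
    "name",
    "n_genes",
    "observed",
    "expected",
    "p_empirical",
    "p_studywide",
)


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    """Read per-SNP association p-values from a delimited table.

    The file must carry a header naming the columns ``snp``, ``chrom``,
    ``pos`` and ``p`` (any order, extra columns ignored).  Rows with a
    p-value outside the half-open interval (0, 1] are rejected with an
    error listing the offending line numbers: a p-value of exactly zero
    cannot be Z-transformed downstream.
    """
    df = pd.read_csv(path, sep=r"\s+", dtype={"snp": str, "chrom": str})
    for col in SUMMARY_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    df = df.loc[:, list(SUMMARY_COLUMNS)].copy()

    p = pd.to_numeric(df["p"], errors="coerce")
    bad = df.index[p.isna()]
    if len(bad):
        lines = ", ".join(str(i + 2) for i in bad[:10])
        raise FormatError(f"{path}: non-numeric p-value on line(s) {lines}")
    out_of_range = df.index[(p <= 0) | (p > 1)]
    if len(out_of_range):
        lines = ", ".join(str(i + 2) for i in out_of_range[:10])
        raise FormatError(
            f"{path}: p-value outside (0, 1] on line(s) {lines}"
        )
    df["p"] = p.astype(float)

    pos = pd.to_numeric(df["pos"], errors="coerce")
    if pos.isna().any() or (pos < 1).any():
        raise FormatError(f"{path}: positions must be integers >= 1")
    df["pos"] = pos.astype(np.int64)

    if df["snp"].duplicated().any():
        dup = df.loc[df["snp"].duplicated(), "snp"].iloc[0]
        raise FormatError(f"{path}: duplicate SNP id {dup!r}")
    return df.reset_index(drop=True)


def write_summary_stats(snps: pd.DataFrame, path: str | Path) -> None:
    """Write a summary-statistics table readable by :func:`read_summary_stats`."""
    df = snps.loc[:, list(SUMMARY_COLUMNS)].copy()
    df["p"] = df["p"].map(lambda v: format(v, ".17g"))
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene models (BED4)
# ---------------------------------------------------------------------------


def read_gene_models(path: str | Path) -> pd.DataFrame:
    """Read gene models from a BED4 file.

    BED's 0-based half-open ``[chromStart, chromEnd)`` becomes the internal
    1-based inclusive ``[chromStart + 1, chromEnd]``.
    """
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["chrom", "start", "end", "gene"],
        dtype={"chrom": str, "gene": str},
        comment="#",
    )
    if df["gene"].isna().any():
        raise FormatError(f"{path}: BED4 requires a name in column 4")
    if (df["end"] <= df["start"]).any():
        row = df.index[(df["end"] <= df["start"])][0]
        raise FormatError(
            f"{path}: chromEnd <= chromStart for {df.loc[row, 'gene']!r}"
        )
    if df["gene"].duplicated().any():
        dup = df.loc[df["gene"].duplicated(), "gene"].iloc[0]
        raise FormatError(f"{path}: duplicate gene id {dup!r}")
    out = pd.DataFrame(
        {
            "gene": df["gene"],
            "chrom": df["chrom"],
            "start": df["start"].astype(np.int64) + 1,
            "end": df["end"].astype(np.int64),
        }
    )
    return out.reset_index(drop=True)


def write_gene_models(genes: pd.DataFrame, path: str | Path) -> None:
    """Write gene models as BED4 (converting back to 0-based half-open)."""
    bed = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": genes["start"].astype(np.int64) - 1,
            "end": genes["end"].astype(np.int64),
            "gene": genes["gene"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneSetDb:
    """Named gene categories (GO terms, KEGG pathways) as flat gene sets.

    ``categories`` maps category id to a frozen set of gene ids;
    ``names`` carries the human-readable description from the GMT file.
    The size filter (3–500 member genes after intersecting with the
    eligible gene universe) is applied by :meth:`filter`.
    """

    categories: Mapping[str, frozenset]
    names: Mapping[str, str] = field(default_factory=dict)
    min_size: int = 3
    max_size: int = 500

    def __len__(self) -> int:
        return len(self.categories)

    def __iter__(self) -> Iterator[str]:
        return iter(self.categories)

    def __getitem__(self, category_id: str) -> frozenset:
        return self.categories[category_id]

    def name(self, category_id: str) -> str:
        return self.names.get(category_id, category_id)

    def filter(self, eligible_genes: Iterable[str] | None = None) -> "GeneSetDb":
        """Intersect with the eligible gene universe and apply the size filter.

        Categories retaining between ``min_size`` and ``max_size`` genes
        (inclusive bounds) survive.  Filtering an already-filtered database
        with the same universe is a no-op.
        """
        eligible = None if eligible_genes is None else frozenset(eligible_genes)
        kept: dict[str, frozenset] = {}
        for cid, members in self.categories.items():
            m = members if eligible is None else members & eligible
            if self.min_size <= len(m) <= self.max_size:
                kept[cid] = frozenset(m)
        log.info("gene-set filter retained %d/%d categories", len(kept), len(self))
        names = {cid: self.names.get(cid, cid) for cid in kept}
        return GeneSetDb(kept, names, self.min_size, self.max_size)


def read_gene_sets(
    path: str | Path,
    eligible_genes: Iterable[str] | None = None,
    min_size: int = 3,
    max_size: int = 500,
) -> GeneSetDb:
    """Read a GMT file and apply the category size filter.

    ``eligible_genes`` is the set of gene ids with at least one mapped SNP
    (the testable universe); GMT members outside it are dropped with a
    logged warning, never an error — public gene-set exports always carry
    unmappable identifiers.
    """
    categories: dict[str, frozenset] = {}
    names: dict[str, str] = {}
    n_unknown = 0
    eligible = None if eligible_genes is None else frozenset(eligible_genes)
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: GMT line with fewer than 3 fields")
            cid, desc, members = parts[0], parts[1], parts[2:]
            if cid in categories:
                raise FormatError(f"{path}: duplicate category id {cid!r}")
            member_set = frozenset(g for g in members if g)
            if eligible is not None:
                n_unknown += len(member_set - eligible)
            categories[cid] = member_set
            names[cid] = desc
    if not categories:
        raise FormatError(f"{path}: empty GMT file")
    if n_unknown:
        log.warning(
            "%s: dropped %d gene ids absent from the gene models", path, n_unknown
        )
    db = GeneSetDb(categories, names, min_size, max_size)
    return db.filter(eligible)


def write_gene_sets(db: GeneSetDb, path: str | Path) -> None:
    """Write a :class:`GeneSetDb` as a GMT file (members sorted for stability)."""
    with open(path, "w") as fh:
        for cid in sorted(db.categories):
            members = "\t".join(sorted(db.categories[cid]))
            fh.write(f"{cid}\t{db.name(cid)}\t{members}\n")


# ---------------------------------------------------------------------------
# LD table
# ---------------------------------------------------------------------------


class LdTable:
    """Symmetric pairwise r² lookup.

    Pairs absent from the table are treated as r² = 0 (independent): LD
    tables conventionally omit sub-threshold pairs.  The table is the
    interchange format for LD — the methods consume r² values, never
    genotypes.
    """

    def __init__(self, records: Iterable[tuple[str, str, float]] = ()) -> None:
        self._r2: dict[tuple[str, str], float] = {}
        self._neighbors: dict[str, list[tuple[str, float]]] | None = None
        for a, b, r2 in records:
            self.add(a, b, r2)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add(self, a: str, b: str, r2: float) -> None:
        if not 0.0 <= r2 <= 1.0:
            raise FormatError(f"r² out of range for pair ({a}, {b}): {r2}")
        if a == b:
            return
        self._r2[self._key(a, b)] = float(r2)
        self._neighbors = None

    def r2(self, a: str, b: str) -> float:
        return self._r2.get(self._key(a, b), 0.0)

    def neighbors(self, snp: str) -> list[tuple[str, float]]:
        """All partners of ``snp`` present in the table, with their r²."""
        if self._neighbors is None:
            adj: dict[str, list[tuple[str, float]]] = {}
            for (a, b), r2 in self._r2.items():
                adj.setdefault(a, []).append((b, r2))
                adj.setdefault(b, []).append((a, r2))
            self._neighbors = adj
        return self._neighbors.get(snp, [])

    def __len__(self) -> int:
        return len(self._r2)

    def __iter__(self) -> Iterator[tuple[str, str, float]]:
        for (a, b), r2 in self._r2.items():
            yield a, b, r2


def read_ld_table(path: str | Path) -> LdTable:
    df = pd.read_csv(path, sep=r"\s+", dtype={"snp_a": str, "snp_b": str})
    for col in ("snp_a", "snp_b", "r2"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return LdTable(zip(df["snp_a"], df["snp_b"], df["r2"].astype(float)))


def write_ld_table(ld: LdTable, path: str | Path) -> None:
    rows = sorted((a, b, r2) for a, b, r2 in ld)
    with open(path, "w") as fh:
        fh.write("snp_a\tsnp_b\tr2\n")
        for a, b, r2 in rows:
            fh.write(f"{a}\t{b}\t{format(r2, '.17g')}\n")


# ---------------------------------------------------------------------------
# study metadata
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StudyMeta:
    """Identity and sample size of one study (meta-analysis weight source)."""

    study_id: str
    n_subjects: int

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError(f"n_subjects must be positive: {self.n_subjects}")


def read_study_meta(path: str | Path) -> list[StudyMeta]:
    df = pd.read_csv(path, sep=r"\s+", dtype={"study_id": str})
    for col in ("study_id", "n_subjects"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return [
        StudyMeta(str(r.study_id), int(r.n_subjects)) for r in df.itertuples()
    ]


def write_study_meta(metas: Iterable[StudyMeta], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("study_id\tn_subjects\n")
        for m in metas:
            fh.write(f"{m.study_id}\t{m.n_subjects}\n")


# ---------------------------------------------------------------------------
# enrichment tables
# ---------------------------------------------------------------------------


def write_enrichment_table(results, path: str | Path) -> None:
    """Write per-category enrichment results as a TSV.

    ``results`` is a non-empty sequence of objects with attributes
    ``category_id``, ``name``, ``n_genes``, ``observed``, ``expected``,
    ``p_empirical`` and optionally ``p_studywide`` (the column layout of
    a per-study enrichment report).  P-values are rendered in scientific
    notation with enough digits to round-trip.
    """
    results = list(results)
    if not results:
        raise ValueError("refusing to write an empty enrichment table")
    rows = []
    for r in results:
        sw = getattr(r, "p_studywide", None)
        rows.append(
            {
                "category": r.category_id,
                "name": getattr(r, "name", r.category_id),
                "n_genes": int(r.n_genes),
                "observed": int(r.observed),
                "expected": format(float(r.expected), ".12E"),
                "p_empirical": format(float(r.p_empirical), ".12E"),
                "p_studywide": "NA" if sw is None else format(float(sw), ".12E"),
            }
        )
    pd.DataFrame(rows, columns=list(ENRICHMENT_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def read_enrichment_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", dtype={"category": str, "name": str}, na_values=["NA"]
    )
    for col in ENRICHMENT_COLUMNS[:-1]:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return df


# ---------------------------------------------------------------------------
# run metadata sidecar
# ---------------------------------------------------------------------------


def write_run_metadata(path: str | Path, params: Mapping) -> None:
    """Write the JSON sidecar echoing seeds, thresholds and versions."""
    from . import __version__

    payload = {"pathgwas_version": __version__, **dict(params)}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
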