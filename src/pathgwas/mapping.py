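"""SNP-to-gene assignment, LD pruning, gene scoring and proximity collapsing.

These are the shared substrate of both enrichment methods: SNPs are assigned
to every gene whose span (plus a 20 kb flank on each side) contains them; the
SNP list is then pruned so that no two retained SNPs within 1 Mb have
r² > 0.2, keeping the most significant SNP of each correlated group; genes
are scored by their best (smallest) SNP p-value; and genes of one category
lying within 1 Mb of each other can be collapsed into single counting
entities so a single association signal spanning a gene cluster is not
counted multiple times.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import LdTable

log = logging.getLogger(__name__)

DEFAULT_FLANK_BP = 20_000
DEFAULT_R2_MAX = 0.2
DEFAULT_WINDOW_BP = 1_000_000
DEFAULT_GAP_BP = 1_000_000


@dataclass
class SnpGeneMap:
    """Bidirectional SNP ↔ gene assignment after flanking-window mapping.

    ``snp_to_genes`` covers every input SNP (unmapped SNPs map to the empty
    set); ``gene_to_snps`` covers every gene that received at least one SNP.
    The two directions are mutually consistent by construction.
    """

    snp_to_genes: dict[str, frozenset]
    gene_to_snps: dict[str, frozenset]
    flank_bp: int = DEFAULT_FLANK_BP

    @property
    def mapped_genes(self) -> frozenset:
        """Genes tagged by at least one SNP."""
        return frozenset(g for g, s in self.gene_to_snps.items() if s)

    def restrict_to_snps(self, snp_ids: Iterable[str]) -> "SnpGeneMap":
        """The same map restricted to a subset of SNPs (e.g. after pruning)."""
        keep = frozenset(snp_ids)
        s2g = {s: g for s, g in self.snp_to_genes.items() if s in keep}
        g2s: dict[str, set] = {}
        for s, genes in s2g.items():
            for g in genes:
                g2s.setdefault(g, set()).add(s)
        return SnpGeneMap(
            s2g, {g: frozenset(v) for g, v in g2s.items()}, self.flank_bp
        )


@dataclass(frozen=True)
class GeneScore:
    """A gene's best-SNP score: the most significant p among its SNPs."""

    gene_id: str
    best_p: float
    best_snp: str
    n_snps: int


@dataclass(frozen=True)
class CollapsedCategory:
    """A category whose physically proximal genes are merged into entities.

    Each entity (a frozenset of gene ids) is one counting unit; genes less
    than ``gap_bp`` apart edge-to-edge on the same chromosome chain
    transitively into one entity.
    """

    category_id: str
    entities: tuple
    gap_bp: int = DEFAULT_GAP_BP


def map_snps_to_genes(
    snps: pd.DataFrame,
    genes: pd.DataFrame,
    flank_bp: int = DEFAULT_FLANK_BP,
) -> SnpGeneMap:
    """Assign each SNP to every gene whose flanked window contains it.

    A SNP at distance exactly ``flank_bp`` from a gene edge is mapped
    (inclusive boundary).  A SNP inside overlapping windows of several genes
    maps to all of them.  SNPs hitting no window stay in the map's domain
    with an empty gene set.
    """
    trees: dict[str, IntervalTree] = {}
    for row in genes.itertuples():
        lo = row.start - flank_bp
        hi = row.end + flank_bp + 1  # interval tree is half-open
        trees.setdefault(row.chrom, IntervalTree()).addi(lo, hi, row.gene)

    snp_to_genes: dict[str, frozenset] = {}
    gene_to_snps: dict[str, set] = {g: set() for g in genes["gene"]}
    for row in snps.itertuples():
        tree = trees.get(row.chrom)
        hits = frozenset(iv.data for iv in tree[row.pos]) if tree else frozenset()
        snp_to_genes[row.snp] = hits
        for g in hits:
            gene_to_snps[g].add(row.snp)
    return SnpGeneMap(
        snp_to_genes,
        {g: frozenset(v) for g, v in gene_to_snps.items()},
        flank_bp,
    )


def ld_prune(
    snps: pd.DataFrame,
    ld: LdTable,
    r2_max: float = DEFAULT_R2_MAX,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> pd.DataFrame:
    """Greedy LD pruning: keep the most significant SNP of each LD group.

    SNPs are visited by ascending p (ties by position, then id); a SNP is
    dropped when a previously retained SNP on the same chromosome within
    ``window_bp`` (inclusive) has r² > ``r2_max`` with it.  Pairs absent
    from the LD table count as independent (r² = 0).  The retained set is
    maximal: adding back any dropped SNP would violate the constraint.
    """
    order = snps.sort_values(["p", "pos", "snp"], kind="mergesort")
    kept: dict[str, tuple[str, int]] = {}
    for row in order.itertuples():
        ok = True
        for other, r2 in ld.neighbors(row.snp):
            if r2 > r2_max and other in kept:
                ochrom, opos = kept[other]
                if ochrom == row.chrom and abs(opos - row.pos) <= window_bp:
                    ok = False
                    break
        if ok:
            kept[row.snp] = (row.chrom, int(row.pos))
    return snps.loc[snps["snp"].isin(kept)].reset_index(drop=True)


def best_gene_pvalue(
    snp_map: SnpGeneMap, snps: pd.DataFrame
) -> list[GeneScore]:
    """Score each mapped gene by the most significant p among its SNPs.

    Genes whose SNP set is empty (or entirely absent from ``snps``, e.g.
    after pruning) are excluded with a logged message.
    """
    p_by_snp = dict(zip(snps["snp"], snps["p"].astype(float)))
    scores: list[GeneScore] = []
    n_dropped = 0
    for gene, snp_ids in sorted(snp_map.gene_to_snps.items()):
        present = [s for s in snp_ids if s in p_by_snp]
        if not present:
            n_dropped += 1
            continue
        best = min(present, key=lambda s: (p_by_snp[s], s))
        scores.append(GeneScore(gene, p_by_snp[best], best, len(present)))
    if n_dropped:
        log.info("best_gene_pvalue: excluded %d genes with no SNP", n_dropped)
    return scores


def collapse_proximal_genes(
    category_genes: Iterable[str],
    genes: pd.DataFrame,
    gap_bp: int = DEFAULT_GAP_BP,
    category_id: str = "",
) -> CollapsedCategory:
    """Merge category genes less than ``gap_bp`` apart into single entities.

    Distance is edge-to-edge between gene spans; merging chains
    transitively (single linkage), so three genes at consecutive 0.4 Mb
    gaps form one entity even though the outer pair is 0.8 Mb apart.
    Genes on different chromosomes never share an entity.
    """
    members = set(category_genes)
    sub = genes.loc[genes["gene"].isin(members)]
    missing = members - set(sub["gene"])
    if missing:
        raise KeyError(f"unresolvable gene ids: {sorted(missing)[:5]}")
    entities: list[frozenset] = []
    for _, chrom_genes in sub.groupby("chrom", sort=True):
        ordered = chrom_genes.sort_values(["start", "end", "gene"])
        current: list[str] = []
        reach = -np.inf  # furthest end seen in the current chain
        for row in ordered.itertuples():
            if current and row.start - reach >= gap_bp:
                entities.append(frozenset(current))
                current = []
                reach = -np.inf
            current.append(row.gene)
            reach = max(reach, row.end)
        if current:
            entities.append(frozenset(current))
    entities.sort(key=lambda e: sorted(e)[0])
    return CollapsedCategory(category_id, tuple(entities), gap_bp)
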