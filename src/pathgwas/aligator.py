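"""Permutation-based overrepresentation analysis of gene categories.

The method selects the genes tagged by LD-pruned SNPs more significant than
a chosen threshold (one of 0.001, 0.005, 0.01, 0.05) and asks, for every
category, whether it contains more of those genes than expected by chance.
The null is built by drawing random replicate gene lists of the same size
*n*: SNPs are sampled uniformly without replacement from the pruned set and
their tagged genes accumulated until exactly *n* distinct genes are reached
(draws that would overshoot are rejected).  Sampling SNPs rather than genes
preserves the bias that SNP-dense genes enter lists more often.

On top of the per-category empirical p-value the module provides a
bootstrap study-wide significance (pseudo-studies built from the replicate
ensemble, each scored against a with-replacement subsample of lists) and
the excess-of-enriched-categories statistic (how many categories beat a
p-value threshold, compared to the same count in pseudo-studies).

All empirical p-values use the add-one estimator (r + 1) / (R + 1), which
never returns zero and gives the floor 1/(R + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GeneSetDb, LdTable
from .mapping import (
    DEFAULT_FLANK_BP,
    DEFAULT_GAP_BP,
    DEFAULT_R2_MAX,
    DEFAULT_WINDOW_BP,
    SnpGeneMap,
    collapse_proximal_genes,
    ld_prune,
    map_snps_to_genes,
)

log = logging.getLogger(__name__)

SNP_THRESHOLDS = (0.001, 0.005, 0.01, 0.05)
CATEGORY_THRESHOLDS = (0.005, 0.01, 0.05)
DEFAULT_N_REPLICATES = 50_000
DEFAULT_N_BOOT = 1_000
DEFAULT_SUBSAMPLE = 5_000


@dataclass(frozen=True)
class SignificantGeneList:
    """Genes tagged by at least one pruned SNP below the SNP threshold."""

    snp_threshold: float
    gene_ids: frozenset

    @property
    def n(self) -> int:
        return len(self.gene_ids)


@dataclass
class ReplicateEnsemble:
    """Random replicate gene lists drawn by SNP sampling.

    ``lists`` holds integer gene indices into ``genes`` (the taggable gene
    universe); every list has exactly ``n`` genes.
    """

    genes: list
    lists: list
    n: int
    rng_seed: object = None

    @property
    def n_replicates(self) -> int:
        return len(self.lists)


@dataclass
class EnrichmentResult:
    """Observed vs expected significant-gene count for one category."""

    category_id: str
    name: str
    n_genes: int
    observed: int
    expected: float
    p_empirical: float
    p_studywide: float | None = None


@dataclass
class AligatorResult:
    """Per-study output: category results plus the excess report.

    ``counts`` (replicates × categories) and ``p_empirical_by_category``
    are retained so the multi-study layer can rerun the bootstrap on a
    restricted category subset without resampling.
    """

    study_id: str
    snp_threshold: float
    significant: SignificantGeneList
    results: dict
    excess: pd.DataFrame
    category_ids: list
    counts: np.ndarray
    ensemble: ReplicateEnsemble

    def p_empirical(self, category_id: str) -> float:
        return self.results[category_id].p_empirical

    def significant_categories(self, category_threshold: float) -> frozenset:
        return frozenset(
            c for c, r in self.results.items()
            if r.p_empirical < category_threshold
        )


# ---------------------------------------------------------------------------
# gene selection and replicate sampling
# ---------------------------------------------------------------------------


def select_significant_genes(
    pruned_map: SnpGeneMap, snps: pd.DataFrame, snp_threshold: float
) -> SignificantGeneList:
    """Genes tagged by pruned SNPs with p strictly below the threshold.

    A SNP tagging several genes contributes all of them; each gene counts
    once however many significant SNPs tag it.
    """
    sig = snps.loc[snps["p"] < snp_threshold, "snp"]
    genes: set = set()
    for s in sig:
        genes |= pruned_map.snp_to_genes.get(s, frozenset())
    if not genes:
        log.warning("no significant genes at SNP threshold %g", snp_threshold)
    return SignificantGeneList(snp_threshold, frozenset(genes))


def _snp_gene_arrays(
    pruned_map: SnpGeneMap,
) -> tuple[list, list, dict]:
    """Pruned SNP order, per-SNP gene index arrays, and the gene index."""
    genes = sorted(pruned_map.mapped_genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    snp_ids = sorted(pruned_map.snp_to_genes)
    snp_genes = [
        np.array(
            sorted(gene_index[g] for g in pruned_map.snp_to_genes[s]),
            dtype=np.int64,
        )
        for s in snp_ids
    ]
    return genes, snp_genes, gene_index


def sample_replicate_list(
    snp_genes: Sequence[np.ndarray],
    n: int,
    n_genes: int,
    rng: np.random.Generator,
    max_restarts: int = 1000,
) -> np.ndarray:
    """Draw one replicate list of exactly ``n`` distinct genes.

    SNPs are drawn uniformly without replacement; a SNP tagging no gene
    consumes a draw and adds nothing; a draw whose genes would push the
    list past ``n`` is rejected and sampling continues.  Returns sorted
    gene indices.
    """
    if n > n_genes:
        raise ValueError(f"cannot reach {n} genes: only {n_genes} taggable")
    if n == 0:
        return np.empty(0, dtype=np.int64)
    n_snps = len(snp_genes)
    for _ in range(max_restarts):
        mask = np.zeros(n_genes, dtype=bool)
        count = 0
        for si in rng.permutation(n_snps):
            gs = snp_genes[si]
            if gs.size == 0:
                continue
            new = gs[~mask[gs]]
            if count + new.size > n:
                continue  # overshoot: reject this draw
            if new.size:
                mask[new] = True
                count += new.size
                if count == n:
                    return np.flatnonzero(mask)
        # The rejection rule can strand a permutation short of n
        # (e.g. only multi-gene SNPs remain); restart with a fresh draw.
    raise ValueError(f"could not assemble a replicate list of {n} genes")


def build_replicate_ensemble(
    pruned_map: SnpGeneMap,
    n: int,
    n_replicates: int,
    rng: np.random.Generator,
) -> ReplicateEnsemble:
    """Draw ``n_replicates`` independent replicate gene lists of size ``n``."""
    genes, snp_genes, _ = _snp_gene_arrays(pruned_map)
    lists = [
        sample_replicate_list(snp_genes, n, len(genes), rng)
        for _ in range(n_replicates)
    ]
    return ReplicateEnsemble(genes=genes, lists=lists, n=n)


# ---------------------------------------------------------------------------
# counting and empirical p-values
# ---------------------------------------------------------------------------


def _category_units(
    db: GeneSetDb,
    gene_index: Mapping[str, int],
    collapse: bool,
    genes_df: pd.DataFrame | None,
    gap_bp: int,
) -> tuple[list, list, list]:
    """Member gene indices and counting-unit labels per category.

    Uncollapsed, every gene is its own unit.  Collapsed, genes of one
    proximity entity share a label and the entity counts once however many
    of its genes appear in a list.
    """
    cat_ids = sorted(db.categories)
    member_idx: list[np.ndarray] = []
    unit_labels: list[np.ndarray] = []
    for cid in cat_ids:
        members = sorted(g for g in db.categories[cid] if g in gene_index)
        idx = np.array([gene_index[g] for g in members], dtype=np.int64)
        if collapse:
            if genes_df is None:
                raise ValueError("collapse requires gene models")
            collapsed = collapse_proximal_genes(members, genes_df, gap_bp, cid)
            label_of = {
                g: k for k, ent in enumerate(collapsed.entities) for g in ent
            }
            labels = np.array([label_of[g] for g in members], dtype=np.int64)
        else:
            labels = np.arange(len(members), dtype=np.int64)
        member_idx.append(idx)
        unit_labels.append(labels)
    return cat_ids, member_idx, unit_labels


def _count_units(
    mask: np.ndarray, member_idx: np.ndarray, labels: np.ndarray
) -> int:
    hit = labels[mask[member_idx]]
    if hit.size == 0:
        return 0
    return int(np.unique(hit).size)


def _counts_matrix(
    ensemble: ReplicateEnsemble,
    member_idx: Sequence[np.ndarray],
    unit_labels: Sequence[np.ndarray],
    collapsed: bool,
) -> np.ndarray:
    """(replicates × categories) counting-unit counts."""
    n_genes = len(ensemble.genes)
    n_cat = len(member_idx)
    counts = np.zeros((ensemble.n_replicates, n_cat), dtype=np.int32)
    if not collapsed:
        # vectorized: membership matrix (categories × genes)
        memb = np.zeros((n_cat, n_genes), dtype=bool)
        for c, idx in enumerate(member_idx):
            memb[c, idx] = True
        for r, lst in enumerate(ensemble.lists):
            counts[r] = memb[:, lst].sum(axis=1)
        return counts
    mask = np.zeros(n_genes, dtype=bool)
    for r, lst in enumerate(ensemble.lists):
        mask[lst] = True
        for c in range(n_cat):
            counts[r, c] = _count_units(mask, member_idx[c], unit_labels[c])
        mask[lst] = False
    return counts


def empirical_p(observed: int, replicate_counts: np.ndarray) -> float:
    """(1 + #{replicate count >= observed}) / (1 + R)."""
    r = int(np.count_nonzero(replicate_counts >= observed))
    return (1 + r) / (1 + len(replicate_counts))


def randomized_empirical_p(
    observed: int, replicate_counts: np.ndarray, rng: np.random.Generator
) -> float:
    """Randomized (jittered) empirical p-value for calibration checks.

    Replicate counts are discrete, so the plain empirical p lives on a
    lattice and can never be exactly uniform; the standard randomized
    construction p = (#{count > obs} + U · (1 + #{count == obs})) / (R + 1)
    with U ~ Uniform(0, 1) is exactly Uniform(0, 1) when the observed study
    is exchangeable with the replicates, which makes goodness-of-fit tests
    of null calibration well posed.  Only used for diagnostics — reported
    enrichment p-values are the conservative lattice version.
    """
    gt = int(np.count_nonzero(replicate_counts > observed))
    eq = int(np.count_nonzero(replicate_counts == observed))
    return (gt + rng.uniform() * (1 + eq)) / (1 + len(replicate_counts))


def category_empirical_p(
    observed: SignificantGeneList,
    category_genes: Iterable[str],
    ensemble: ReplicateEnsemble,
    category_id: str = "",
    name: str = "",
) -> EnrichmentResult:
    """Empirical enrichment p for one category against a replicate ensemble."""
    gene_index = {g: i for i, g in enumerate(ensemble.genes)}
    members = sorted(g for g in category_genes if g in gene_index)
    idx = np.array([gene_index[g] for g in members], dtype=np.int64)
    obs = len(observed.gene_ids & set(members))
    memb = np.zeros(len(ensemble.genes), dtype=bool)
    memb[idx] = True
    counts = np.array([int(memb[lst].sum()) for lst in ensemble.lists])
    return EnrichmentResult(
        category_id=category_id,
        name=name or category_id,
        n_genes=len(members),
        observed=obs,
        expected=float(counts.mean()) if counts.size else 0.0,
        p_empirical=empirical_p(obs, counts),
    )


def category_pvalues(
    snps: pd.DataFrame,
    genes: pd.DataFrame,
    gene_sets: GeneSetDb,
    ld: LdTable,
    *,
    snp_threshold: float = 0.05,
    flank_bp: int = DEFAULT_FLANK_BP,
    r2_max: float = DEFAULT_R2_MAX,
    window_bp: int = DEFAULT_WINDOW_BP,
    n_replicates: int = DEFAULT_N_REPLICATES,
    rng: np.random.Generator | int | None = None,
    randomized: bool = False,
) -> dict:
    """Per-category empirical p-values only (no bootstrap layer).

    A light entry point for calibration studies and power scans; with
    ``randomized=True`` the jittered p-values of
    :func:`randomized_empirical_p` are returned instead of the
    conservative lattice values.
    """
    rng = np.random.default_rng(rng)
    full_map = map_snps_to_genes(snps, genes, flank_bp)
    db = gene_sets.filter(full_map.mapped_genes)
    pruned = ld_prune(snps, ld, r2_max, window_bp)
    pruned_map = full_map.restrict_to_snps(pruned["snp"])
    significant = select_significant_genes(pruned_map, pruned, snp_threshold)
    universe, snp_genes, gene_index = _snp_gene_arrays(pruned_map)
    lists = [
        sample_replicate_list(snp_genes, significant.n, len(universe), rng)
        for _ in range(n_replicates)
    ]
    ensemble = ReplicateEnsemble(genes=universe, lists=lists, n=significant.n)
    cat_ids, member_idx, unit_labels = _category_units(
        db, gene_index, False, None, DEFAULT_GAP_BP
    )
    counts = _counts_matrix(ensemble, member_idx, unit_labels, False)
    obs_mask = np.zeros(len(universe), dtype=bool)
    obs_mask[[gene_index[g] for g in significant.gene_ids if g in gene_index]] = True
    out = {}
    for c, cid in enumerate(cat_ids):
        obs = _count_units(obs_mask, member_idx[c], unit_labels[c])
        if randomized:
            out[cid] = randomized_empirical_p(obs, counts[:, c], rng)
        else:
            out[cid] = empirical_p(obs, counts[:, c])
    return out


# ---------------------------------------------------------------------------
# bootstrap: study-wide significance and excess of enriched categories
# ---------------------------------------------------------------------------


def bootstrap_pseudo_p(
    counts: np.ndarray,
    n_boot: int,
    subsample: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Category p-values of ``n_boot`` pseudo-studies under the null.

    Each iteration picks one replicate list as the pseudo-observed study
    and scores every category against ``subsample`` lists drawn from the
    ensemble with replacement.  Returns an (n_boot × categories) array.
    """
    n_rep = counts.shape[0]
    if subsample > n_rep:
        raise ValueError(
            f"subsample ({subsample}) exceeds ensemble size ({n_rep})"
        )
    out = np.empty((n_boot, counts.shape[1]))
    for b in range(n_boot):
        ref = rng.integers(n_rep)
        sub = rng.integers(0, n_rep, size=subsample)
        ge = (counts[sub] >= counts[ref]).sum(axis=0)
        out[b] = (1 + ge) / (1 + subsample)
    return out


def studywide_bootstrap(
    category_ps: Mapping[str, float],
    counts: np.ndarray,
    category_ids: Sequence[str],
    n_boot: int = DEFAULT_N_BOOT,
    subsample: int = DEFAULT_SUBSAMPLE,
    rng: np.random.Generator | None = None,
    pseudo_p: np.ndarray | None = None,
) -> dict:
    """Study-wide p per category: how often a pseudo-study's most
    significant category p is at least as extreme as the category's
    empirical p, with the add-one correction."""
    if pseudo_p is None:
        if rng is None:
            raise ValueError("rng required when pseudo_p not supplied")
        pseudo_p = bootstrap_pseudo_p(counts, n_boot, subsample, rng)
    min_ps = pseudo_p.min(axis=1)
    n_b = pseudo_p.shape[0]
    return {
        c: (1 + int(np.count_nonzero(min_ps <= category_ps[c]))) / (1 + n_b)
        for c in category_ids
    }


def excess_of_enrichment(
    category_ps: Mapping[str, float],
    counts: np.ndarray,
    category_ids: Sequence[str],
    category_thresholds: Sequence[float] = CATEGORY_THRESHOLDS,
    n_boot: int = DEFAULT_N_BOOT,
    subsample: int = DEFAULT_SUBSAMPLE,
    rng: np.random.Generator | None = None,
    pseudo_p: np.ndarray | None = None,
) -> pd.DataFrame:
    """Observed number of categories below each enrichment threshold and
    the bootstrap probability of an equal or larger count by chance."""
    if pseudo_p is None:
        if rng is None:
            raise ValueError("rng required when pseudo_p not supplied")
        pseudo_p = bootstrap_pseudo_p(counts, n_boot, subsample, rng)
    ps = np.array([category_ps[c] for c in category_ids])
    n_b = pseudo_p.shape[0]
    rows = []
    for thr in category_thresholds:
        observed = int(np.count_nonzero(ps < thr))
        null_counts = (pseudo_p < thr).sum(axis=1)
        p_excess = (1 + int(np.count_nonzero(null_counts >= observed))) / (
            1 + n_b
        )
        rows.append(
            {
                "category_threshold": thr,
                "n_enriched": observed,
                "p_excess": p_excess,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full per-study run
# ---------------------------------------------------------------------------


def run_aligator(
    snps: pd.DataFrame,
    genes: pd.DataFrame,
    gene_sets: GeneSetDb,
    ld: LdTable,
    *,
    study_id: str = "study",
    snp_threshold: float = 0.001,
    flank_bp: int = DEFAULT_FLANK_BP,
    r2_max: float = DEFAULT_R2_MAX,
    window_bp: int = DEFAULT_WINDOW_BP,
    n_replicates: int = DEFAULT_N_REPLICATES,
    n_boot: int = DEFAULT_N_BOOT,
    subsample: int = DEFAULT_SUBSAMPLE,
    category_thresholds: Sequence[float] = CATEGORY_THRESHOLDS,
    collapse: bool = False,
    gap_bp: int = DEFAULT_GAP_BP,
    rng: np.random.Generator | int | None = None,
) -> AligatorResult:
    """Run the full overrepresentation analysis for one study.

    Pipeline: map SNPs to flanked gene windows, size-filter the category
    database on genes with >= 1 mapped SNP (pre-pruning map), LD-prune the
    SNPs, select the significant gene list, draw the replicate ensemble,
    and compute per-category empirical p, study-wide bootstrap p and the
    excess report.  With ``collapse=True`` physically proximal genes of a
    category count as one entity in both observed and replicate lists.
    """
    rng = np.random.default_rng(rng)

    full_map = map_snps_to_genes(snps, genes, flank_bp)
    db = gene_sets.filter(full_map.mapped_genes)
    pruned = ld_prune(snps, ld, r2_max, window_bp)
    pruned_map = full_map.restrict_to_snps(pruned["snp"])

    significant = select_significant_genes(pruned_map, pruned, snp_threshold)
    universe, snp_genes, gene_index = _snp_gene_arrays(pruned_map)
    n = significant.n
    lists = [
        sample_replicate_list(snp_genes, n, len(universe), rng)
        for _ in range(n_replicates)
    ]
    ensemble = ReplicateEnsemble(genes=universe, lists=lists, n=n)

    cat_ids, member_idx, unit_labels = _category_units(
        db, gene_index, collapse, genes, gap_bp
    )
    counts = _counts_matrix(ensemble, member_idx, unit_labels, collapse)

    obs_mask = np.zeros(len(universe), dtype=bool)
    obs_idx = [gene_index[g] for g in significant.gene_ids if g in gene_index]
    obs_mask[obs_idx] = True

    results: dict[str, EnrichmentResult] = {}
    p_emp: dict[str, float] = {}
    for c, cid in enumerate(cat_ids):
        obs = _count_units(obs_mask, member_idx[c], unit_labels[c])
        p = empirical_p(obs, counts[:, c])
        results[cid] = EnrichmentResult(
            category_id=cid,
            name=db.name(cid),
            n_genes=len(member_idx[c]),
            observed=obs,
            expected=float(counts[:, c].mean()),
            p_empirical=p,
        )
        p_emp[cid] = p

    pseudo_p = bootstrap_pseudo_p(counts, n_boot, min(subsample, n_replicates), rng)
    sw = studywide_bootstrap(p_emp, counts, cat_ids, pseudo_p=pseudo_p)
    for cid in cat_ids:
        results[cid].p_studywide = sw[cid]
    excess = excess_of_enrichment(
        p_emp, counts, cat_ids, category_thresholds, pseudo_p=pseudo_p
    )

    return AligatorResult(
        study_id=study_id,
        snp_threshold=snp_threshold,
        significant=significant,
        results=results,
        excess=excess,
        category_ids=list(cat_ids),
        counts=counts,
        ensemble=ensemble,
    )
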