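"""Synthetic multi-study GWAS summary statistics with planted pathway signal.

The generator emulates the statistical structure the enrichment methods
assume, not human genome realism: genes laid out sequentially along
chromosomes with random spans and gaps; SNPs placed in flanked gene windows
(plus optional intergenic SNPs tagging nothing); block LD with a constant
within-block r² so the 0.2/1 Mb pruning rule is exercised; null SNP
p-values uniform on (0, 1); and a configurable number of planted categories
in which a fraction of member genes each receive one causal SNP whose
p-value follows Beta(a, 1) with a < 1 — mass concentrated near zero, with
the analytic tail Pr(p < t) = t^a.  Signal genes can be shared across
studies (replication scenario) or redrawn per study (independent signal).

Everything is deterministic given the configuration seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .io import GeneSetDb, LdTable, StudyMeta
from .mapping import DEFAULT_FLANK_BP, map_snps_to_genes

log = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic multi-study benchmark.

    Defaults describe a small two-chromosome genome with three studies
    whose sample sizes follow the family/case-control/population trio the
    replication design expects, moderate block LD above the pruning
    threshold, and five planted categories with a Beta(0.15, 1) signal in
    40% of member genes.
    """

    n_chroms: int = 2
    n_genes: int = 200
    gene_span_bp: tuple = (5_000, 20_000)
    intergenic_bp: tuple = (20_000, 80_000)
    snps_per_gene: tuple = (3, 8)
    n_intergenic_snps: int = 20
    ld_block_size: int = 4
    within_block_r2: float = 0.8
    n_categories: int = 100
    category_size: tuple = (5, 30)
    n_planted: int = 5
    planted_size: int | None = None
    signal_gene_fraction: float = 0.4
    signal_beta_a: float = 0.15
    n_studies: int = 3
    study_n_subjects: tuple = (4038, 2014, 5198)
    shared_signal: bool = True
    flank_bp: int = DEFAULT_FLANK_BP
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.category_size
        if not (3 <= lo <= hi <= 500):
            raise ValueError("category sizes must lie within [3, 500]")
        if not 0.0 <= self.within_block_r2 <= 1.0:
            raise ValueError("within_block_r2 must lie in [0, 1]")
        if not 0.0 < self.signal_gene_fraction <= 1.0:
            raise ValueError("signal_gene_fraction must lie in (0, 1]")
        if self.n_studies > len(self.study_n_subjects):
            raise ValueError("study_n_subjects shorter than n_studies")
        if self.gene_span_bp[0] > self.gene_span_bp[1] or self.gene_span_bp[0] < 1:
            raise ValueError("infeasible gene_span_bp range")
        if self.intergenic_bp[0] > self.intergenic_bp[1] or self.intergenic_bp[0] < 0:
            raise ValueError("infeasible intergenic_bp range")


@dataclass
class SyntheticTruth:
    """Ground truth of the planted signal, for recovery tests."""

    planted_category_ids: frozenset
    signal_genes_by_study: dict
    causal_snp_by_study: dict
    seed: int
    config: SimulationConfig

    def to_json(self) -> str:
        payload = {
            "planted_category_ids": sorted(self.planted_category_ids),
            "signal_genes_by_study": {
                k: sorted(v) for k, v in self.signal_genes_by_study.items()
            },
            "causal_snp_by_study": {
                k: dict(sorted(v.items())) for k, v in self.causal_snp_by_study.items()
            },
            "seed": self.seed,
            "config": dataclasses.asdict(self.config),
        }
        return json.dumps(payload, indent=2, sort_keys=True)


@dataclass
class SyntheticDataset:
    """One fully generated benchmark: genome, LD, categories, studies, truth."""

    genes: pd.DataFrame
    snps: pd.DataFrame  # snp, chrom, pos (no p)
    ld: LdTable
    gene_sets: GeneSetDb
    studies: dict  # study_id -> summary-stat DataFrame
    study_meta: list
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# genome and SNP map
# ---------------------------------------------------------------------------


def simulate_genome(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Lay out genes sequentially per chromosome and place SNPs.

    Each gene receives a uniform number of SNPs inside its flanked window;
    ``n_intergenic_snps`` additional SNPs land midway between consecutive
    gene windows (tagging nothing when the gap allows).  Returns
    ``(genes, snps)`` with 1-based inclusive coordinates.
    """
    genes_rows = []
    if config.n_genes:
        per_chrom = np.array_split(np.arange(config.n_genes), config.n_chroms)
    else:
        per_chrom = []
    for ci, idxs in enumerate(per_chrom):
        pos = 1
        for gi in idxs:
            gap = int(rng.integers(config.intergenic_bp[0], config.intergenic_bp[1] + 1))
            span = int(rng.integers(config.gene_span_bp[0], config.gene_span_bp[1] + 1))
            start = pos + gap
            genes_rows.append(
                {
                    "gene": f"G{gi:05d}",
                    "chrom": f"chr{ci + 1}",
                    "start": start,
                    "end": start + span - 1,
                }
            )
            pos = start + span
    genes = pd.DataFrame(
        genes_rows, columns=["gene", "chrom", "start", "end"]
    )

    snp_rows = []
    counter = 0
    for row in genes.itertuples():
        k = int(rng.integers(config.snps_per_gene[0], config.snps_per_gene[1] + 1))
        lo = max(1, row.start - config.flank_bp)
        hi = row.end + config.flank_bp
        positions = np.sort(rng.integers(lo, hi + 1, size=k))
        for p in positions:
            snp_rows.append(
                {"snp": f"rs{counter:06d}", "chrom": row.chrom, "pos": int(p)}
            )
            counter += 1
    # intergenic SNPs: halfway between consecutive flanked windows
    if len(genes) >= 2 and config.n_intergenic_snps:
        gaps = []
        for chrom, grp in genes.groupby("chrom"):
            g = grp.sort_values("start")
            for (_, a), (_, b) in zip(g.iterrows(), g.iloc[1:].iterrows()):
                lo = a["end"] + config.flank_bp + 1
                hi = b["start"] - config.flank_bp - 1
                if hi > lo:
                    gaps.append((chrom, lo, hi))
        for _ in range(config.n_intergenic_snps):
            if not gaps:
                break
            chrom, lo, hi = gaps[int(rng.integers(len(gaps)))]
            snp_rows.append(
                {
                    "snp": f"rs{counter:06d}",
                    "chrom": chrom,
                    "pos": int(rng.integers(lo, hi + 1)),
                }
            )
            counter += 1
    snps = pd.DataFrame(snp_rows, columns=["snp", "chrom", "pos"])
    snps = snps.sort_values(["chrom", "pos", "snp"]).reset_index(drop=True)
    return genes, snps


def simulate_ld(
    snps: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> LdTable:
    """Block LD: position-consecutive SNPs grouped into fixed-size blocks.

    All pairs within a block get r² = ``within_block_r2``; cross-block
    pairs are omitted (r² = 0).  Block size 1 yields an empty table.
    """
    ld = LdTable()
    if config.ld_block_size <= 1 or config.within_block_r2 == 0.0:
        return ld
    for _, grp in snps.groupby("chrom"):
        ids = grp.sort_values(["pos", "snp"])["snp"].tolist()
        for b in range(0, len(ids), config.ld_block_size):
            block = ids[b : b + config.ld_block_size]
            for i in range(len(block)):
                for j in range(i + 1, len(block)):
                    ld.add(block[i], block[j], config.within_block_r2)
    return ld


# ---------------------------------------------------------------------------
# categories and planted truth
# ---------------------------------------------------------------------------


def simulate_categories(
    genes: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> tuple[GeneSetDb, frozenset]:
    """Draw gene categories (overlap across categories allowed) and flag
    the planted ones.

    Planted categories are the first ``n_planted`` and use
    ``planted_size`` members when set (otherwise the drawn size)."""
    gene_ids = genes["gene"].to_numpy()
    lo, hi = config.category_size
    if hi > len(gene_ids):
        raise ValueError("category_size max exceeds the number of genes")
    categories: dict[str, frozenset] = {}
    names: dict[str, str] = {}
    planted = []
    for k in range(config.n_categories):
        cid = f"CAT{k:04d}"
        if k < config.n_planted:
            size = config.planted_size or int(rng.integers(lo, hi + 1))
            if size > len(gene_ids):
                raise ValueError("planted_size exceeds the number of genes")
            planted.append(cid)
            names[cid] = "planted category"
        else:
            size = int(rng.integers(lo, hi + 1))
            names[cid] = "background category"
        members = rng.choice(gene_ids, size=size, replace=False)
        categories[cid] = frozenset(members.tolist())
    db = GeneSetDb(categories, names)
    return db, frozenset(planted)


def _draw_signal_assignment(
    db: GeneSetDb,
    planted: frozenset,
    snp_map,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[frozenset, dict]:
    """Pick signal genes in each planted category and one causal SNP each."""
    signal_genes: set = set()
    causal: dict[str, str] = {}
    for cid in sorted(planted):
        members = sorted(db.categories[cid])
        k = max(1, int(round(config.signal_gene_fraction * len(members))))
        chosen = rng.choice(members, size=k, replace=False)
        signal_genes.update(chosen.tolist())
    for g in sorted(signal_genes):
        tags = sorted(snp_map.gene_to_snps.get(g, frozenset()))
        if not tags:
            log.warning("signal gene %s has no tagging SNP; skipped", g)
            continue
        causal[g] = tags[int(rng.integers(len(tags)))]
    return frozenset(causal), causal


def simulate_study_pvalues(
    snps: pd.DataFrame,
    signal_causal: dict,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-SNP association p-values for one study.

    Null SNPs draw p ~ Uniform(0, 1); each signal gene's causal SNP draws
    p ~ Beta(signal_beta_a, 1) instead.
    """
    p = rng.uniform(size=len(snps))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    out = snps.copy()
    out["p"] = p
    if signal_causal:
        causal_snps = sorted(set(signal_causal.values()))
        beta = rng.beta(config.signal_beta_a, 1.0, size=len(causal_snps))
        beta = np.clip(beta, np.finfo(float).tiny, 1.0)
        idx = pd.Index(out["snp"]).get_indexer(causal_snps)
        out.iloc[idx, out.columns.get_loc("p")] = beta
    return out


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate the complete multi-study benchmark for one configuration.

    Independent RNG streams are split from the configuration seed in a
    fixed documented order (genome, LD, categories, signal assignment,
    then one stream per study), so outputs are reproducible bit-for-bit.
    """
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(4 + config.n_studies)
    rng_genome = np.random.default_rng(streams[0])
    rng_ld = np.random.default_rng(streams[1])
    rng_cat = np.random.default_rng(streams[2])
    rng_sig = np.random.default_rng(streams[3])

    genes, snps = simulate_genome(config, rng_genome)
    ld = simulate_ld(snps, config, rng_ld)
    db, planted = simulate_categories(genes, config, rng_cat)
    snp_map = map_snps_to_genes(snps, genes, config.flank_bp)

    shared_sig: dict | None = None
    if config.shared_signal and planted:
        _, shared_sig = _draw_signal_assignment(db, planted, snp_map, config, rng_sig)

    studies: dict[str, pd.DataFrame] = {}
    metas: list[StudyMeta] = []
    signal_by_study: dict = {}
    causal_by_study: dict = {}
    for s in range(config.n_studies):
        sid = f"STUDY{s + 1}"
        rng_study = np.random.default_rng(streams[4 + s])
        if not planted:
            causal: dict = {}
        elif config.shared_signal:
            causal = shared_sig
        else:
            _, causal = _draw_signal_assignment(
                db, planted, snp_map, config, rng_study
            )
        studies[sid] = simulate_study_pvalues(snps, causal, config, rng_study)
        metas.append(StudyMeta(sid, int(config.study_n_subjects[s])))
        signal_by_study[sid] = frozenset(causal)
        causal_by_study[sid] = dict(causal)

    truth = SyntheticTruth(
        planted_category_ids=planted,
        signal_genes_by_study=signal_by_study,
        causal_snp_by_study=causal_by_study,
        seed=config.seed,
        config=config,
    )
    return SyntheticDataset(
        genes=genes,
        snps=snps,
        ld=ld,
        gene_sets=db,
        studies=studies,
        study_meta=metas,
        truth=truth,
    )


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict:
    """Write the benchmark in the pipeline's file formats; return the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genes": outdir / "genes.bed",
        "gene_sets": outdir / "gene_sets.gmt",
        "ld": outdir / "ld.tsv",
        "study_meta": outdir / "study_meta.tsv",
        "truth": outdir / "truth.json",
    }
    gio.write_gene_models(dataset.genes, paths["genes"])
    gio.write_gene_sets(dataset.gene_sets, paths["gene_sets"])
    gio.write_ld_table(dataset.ld, paths["ld"])
    gio.write_study_meta(dataset.study_meta, paths["study_meta"])
    paths["truth"].write_text(dataset.truth.to_json() + "\n")
    for sid, df in dataset.studies.items():
        p = outdir / f"{sid}.summary.tsv"
        gio.write_summary_stats(df, p)
        paths[sid] = p
    return {k: str(v) for k, v in paths.items()}
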