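"""End-to-end orchestration: simulate → map → enrich per study → replicate.

Stages hand results to each other through plain files in the output
directory (inspectable and resumable), and every parameter plus the seed is
echoed into a JSON metadata sidecar.  Re-running with the same configuration
and seed reproduces the outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .aligator import (
    CATEGORY_THRESHOLDS,
    DEFAULT_N_BOOT,
    DEFAULT_N_REPLICATES,
    DEFAULT_SUBSAMPLE,
    run_aligator,
)
from .magenta import DEFAULT_CUTOFF_QUANTILE, DEFAULT_N_PERM, run_magenta
from .mapping import DEFAULT_FLANK_BP, DEFAULT_R2_MAX, DEFAULT_WINDOW_BP
from .replication import (
    StudyEnrichment,
    combine_studies,
    common_enriched,
    overlap_significance,
    replicate_in_third,
)
from .simulate import SimulationConfig, simulate_dataset, write_dataset

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """All pipeline parameters, with defaults mirroring the study design.

    ``simulate`` holds the synthetic-benchmark configuration; set the
    ``*_path`` fields instead to analyze existing files.
    """

    simulate: SimulationConfig | None = None
    snps_paths: dict = field(default_factory=dict)  # study_id -> path
    genes_path: str | None = None
    gene_sets_path: str | None = None
    ld_path: str | None = None
    study_meta_path: str | None = None

    flank_bp: int = DEFAULT_FLANK_BP
    r2_max: float = DEFAULT_R2_MAX
    window_bp: int = DEFAULT_WINDOW_BP
    snp_threshold: float = 0.001
    category_thresholds: tuple = CATEGORY_THRESHOLDS
    n_replicates: int = DEFAULT_N_REPLICATES
    n_boot: int = DEFAULT_N_BOOT
    subsample: int = DEFAULT_SUBSAMPLE
    collapse: bool = False
    run_magenta: bool = True
    cutoff_quantile: float = DEFAULT_CUTOFF_QUANTILE
    n_perm: int = DEFAULT_N_PERM
    alpha: float = 0.05
    seed: int = 0


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - stage naming contract
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc

        return wrapper

    return deco


@_stage("inputs")
def _load_inputs(config: RunConfig, outdir: Path):
    if config.simulate is not None:
        dataset = simulate_dataset(config.simulate)
        paths = write_dataset(dataset, outdir / "inputs")
        snps_paths = {
            m.study_id: paths[m.study_id] for m in dataset.study_meta
        }
        genes_path = paths["genes"]
        gene_sets_path = paths["gene_sets"]
        ld_path = paths["ld"]
        meta_path = paths["study_meta"]
    else:
        snps_paths = dict(config.snps_paths)
        genes_path = config.genes_path
        gene_sets_path = config.gene_sets_path
        ld_path = config.ld_path
        meta_path = config.study_meta_path
    for label, p in [
        ("gene models", genes_path),
        ("gene sets", gene_sets_path),
        ("LD table", ld_path),
        ("study metadata", meta_path),
    ]:
        if p is None or not Path(p).exists():
            raise FileNotFoundError(f"missing {label} file: {p}")
    for sid, p in snps_paths.items():
        if not Path(p).exists():
            raise FileNotFoundError(f"missing summary statistics for {sid}: {p}")
    genes = gio.read_gene_models(genes_path)
    gene_sets = gio.read_gene_sets(gene_sets_path)
    ld = gio.read_ld_table(ld_path)
    metas = gio.read_study_meta(meta_path)
    studies = {sid: gio.read_summary_stats(p) for sid, p in snps_paths.items()}
    return genes, gene_sets, ld, metas, studies


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run every stage; return a summary dict of outputs and paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes, gene_sets, ld, metas, studies = _load_inputs(config, outdir)
    meta_by_id = {m.study_id: m for m in metas}

    seeds = np.random.SeedSequence(config.seed).spawn(2 * len(studies) + 1)
    study_ids = sorted(studies)

    aligator_results = {}
    enrichments = {}
    for i, sid in enumerate(study_ids):
        res = _run_aligator_stage(
            config, sid, studies[sid], genes, gene_sets, ld, seeds[i]
        )
        aligator_results[sid] = res
        enrichments[sid] = StudyEnrichment(
            sid,
            meta_by_id[sid],
            {c: r.p_empirical for c, r in res.results.items()},
        )
        table = sorted(res.results.values(), key=lambda r: r.category_id)
        gio.write_enrichment_table(table, outdir / f"{sid}.aligator.tsv")
        res.excess.to_csv(
            outdir / f"{sid}.excess.tsv", sep="\t", index=False,
            float_format="%.6E",
        )

    if config.run_magenta:
        for i, sid in enumerate(study_ids):
            mg = _run_magenta_stage(
                config, sid, studies[sid], genes, gene_sets, ld,
                seeds[len(study_ids) + i],
            )
            mg.to_csv(
                outdir / f"{sid}.magenta.tsv", sep="\t", index=False,
                float_format="%.6E",
            )

    summary = _run_replication_stage(
        config, study_ids, aligator_results, enrichments, outdir,
        seeds[2 * len(studies)],
    )

    params = dataclasses.asdict(config)
    if config.simulate is not None:
        params["simulate"] = dataclasses.asdict(config.simulate)
    gio.write_run_metadata(outdir / "run_metadata.json", params)
    summary["outdir"] = str(outdir)
    return summary


@_stage("aligator")
def _run_aligator_stage(config, sid, snps, genes, gene_sets, ld, seed_seq):
    return run_aligator(
        snps,
        genes,
        gene_sets,
        ld,
        study_id=sid,
        snp_threshold=config.snp_threshold,
        flank_bp=config.flank_bp,
        r2_max=config.r2_max,
        window_bp=config.window_bp,
        n_replicates=config.n_replicates,
        n_boot=config.n_boot,
        subsample=config.subsample,
        category_thresholds=config.category_thresholds,
        collapse=config.collapse,
        rng=np.random.default_rng(seed_seq),
    )


@_stage("magenta")
def _run_magenta_stage(config, sid, snps, genes, gene_sets, ld, seed_seq):
    return run_magenta(
        snps,
        genes,
        gene_sets,
        ld,
        study_id=sid,
        flank_bp=config.flank_bp,
        r2_max=config.r2_max,
        window_bp=config.window_bp,
        cutoff_quantile=config.cutoff_quantile,
        n_perm=config.n_perm,
        rng=np.random.default_rng(seed_seq),
    )


@_stage("replication")
def _run_replication_stage(
    config, study_ids, aligator_results, enrichments, outdir, seed_seq
):
    summary: dict = {"studies": list(study_ids)}
    if len(study_ids) < 2:
        return summary
    a_id, b_id = study_ids[0], study_ids[1]
    rng = np.random.default_rng(seed_seq)
    rows = []
    for thr in config.category_thresholds:
        common = common_enriched(enrichments[a_id], enrichments[b_id], thr)
        p_overlap = overlap_significance(
            aligator_results[a_id],
            enrichments[b_id].significant(thr),
            thr,
            n_boot=config.n_boot,
            subsample=config.subsample,
            rng=rng,
        )
        rows.append(
            {
                "category_threshold": thr,
                "n_common": len(common),
                "p_overlap": p_overlap,
                "common_ids": ";".join(sorted(common)) or "-",
            }
        )
    common_df = pd.DataFrame(rows)
    common_df.to_csv(
        outdir / "common_categories.tsv", sep="\t", index=False,
        float_format="%.6E",
    )
    widest = common_enriched(
        enrichments[a_id], enrichments[b_id], max(config.category_thresholds)
    )
    summary["n_common"] = {
        r["category_threshold"]: r["n_common"] for r in rows
    }
    summary["p_overlap"] = {
        r["category_threshold"]: r["p_overlap"] for r in rows
    }
    if len(study_ids) >= 3:
        c_id = study_ids[2]
        replicated = replicate_in_third(
            widest, enrichments[c_id], alpha=config.alpha
        )
        summary["replicated_in_third"] = sorted(replicated)
        pd.DataFrame({"category": sorted(replicated)}).to_csv(
            outdir / "replicated_categories.tsv", sep="\t", index=False
        )
    combined = combine_studies([enrichments[s] for s in study_ids])
    combined.to_csv(
        outdir / "combined_pvalues.tsv", sep="\t", index=False,
        float_format="%.12E",
    )
    summary["common_widest"] = sorted(widest)
    return summary


def hash_outputs(outdir: str | Path) -> dict:
    """SHA-256 of every regular file under ``outdir`` (determinism checks)."""
    outdir = Path(outdir)
    out = {}
    for p in sorted(outdir.rglob("*")):
        if p.is_file():
            out[str(p.relative_to(outdir))] = hashlib.sha256(
                p.read_bytes()
            ).hexdigest()
    return out
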