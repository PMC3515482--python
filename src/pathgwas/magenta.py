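"""GSEA-style enrichment from confounder-corrected best-SNP gene scores.

Each gene is scored by the most significant p-value among the SNPs in its
flanked window and the score is normalized to a Z-score, z = Φ⁻¹(1 − p).
Because gene size, SNP density and related structural covariates inflate
best-SNP scores, z is corrected by stepwise multiple linear regression on
six gene-level confounders (gene size, SNPs/kb, independent SNPs/kb,
recombination hotspots/kb, LD units/kb, cM/kb); the corrected score is the
re-standardized residual.  A category's statistic is its leading-edge
count — how many member genes fall in the top 5% (95th percentile) of
corrected scores — compared against the same count in random gene samples
of equal size.  Bonferroni and Benjamini–Hochberg adjustments are applied
across categories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSetDb, LdTable
from .mapping import (
    DEFAULT_FLANK_BP,
    DEFAULT_GAP_BP,
    DEFAULT_R2_MAX,
    DEFAULT_WINDOW_BP,
    GeneScore,
    SnpGeneMap,
    best_gene_pvalue,
    collapse_proximal_genes,
    ld_prune,
    map_snps_to_genes,
)

log = logging.getLogger(__name__)

CONFOUNDER_COLUMNS = (
    "size_kb",
    "snps_per_kb",
    "indep_snps_per_kb",
    "hotspots_per_kb",
    "ld_units_per_kb",
    "cM_per_kb",
)
DEFAULT_CUTOFF_QUANTILE = 0.95
DEFAULT_N_PERM = 10_000


@dataclass
class GseaResult:
    """Leading-edge permutation result for one category."""

    category_id: str
    name: str
    n_genes: int
    observed_leading: int
    expected_leading: float
    p_nominal: float
    p_bonferroni: float | None = None
    fdr: float | None = None


# ---------------------------------------------------------------------------
# confounders
# ---------------------------------------------------------------------------


def compute_confounders(
    genes: pd.DataFrame,
    snp_map: SnpGeneMap,
    pruned_snp_ids: Iterable[str] | None = None,
    hotspots: pd.DataFrame | None = None,
    genetic_map: pd.DataFrame | None = None,
    ld_units: Mapping[str, float] | None = None,
    flank_bp: int = DEFAULT_FLANK_BP,
) -> pd.DataFrame:
    """Per-gene structural covariates over the flanked gene window.

    ``size_kb`` is the window length (span + both flanks) in kb;
    ``snps_per_kb`` counts all mapped SNPs, ``indep_snps_per_kb`` only
    those surviving LD pruning.  ``hotspots`` (columns chrom, pos) and
    ``genetic_map`` (columns chrom, pos, cM, the cumulative genetic
    position) are optional annotation tracks; densities default to zero
    when a track is absent.  LD units per kb is an external construct and
    is taken as an optional per-gene input, defaulting to zero.
    """
    pruned = None if pruned_snp_ids is None else frozenset(pruned_snp_ids)
    if hotspots is None:
        log.info("no hotspot track provided; hotspots_per_kb = 0")
    if genetic_map is None:
        log.info("no genetic map provided; cM_per_kb = 0")

    hot_by_chrom: dict[str, np.ndarray] = {}
    if hotspots is not None:
        for chrom, grp in hotspots.groupby("chrom"):
            hot_by_chrom[str(chrom)] = np.sort(grp["pos"].to_numpy())
    gm_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if genetic_map is not None:
        for chrom, grp in genetic_map.sort_values("pos").groupby("chrom"):
            gm_by_chrom[str(chrom)] = (
                grp["pos"].to_numpy(float),
                grp["cM"].to_numpy(float),
            )

    rows = []
    for row in genes.itertuples():
        lo, hi = row.start - flank_bp, row.end + flank_bp
        size_kb = (row.end - row.start + 1 + 2 * flank_bp) / 1000.0
        snp_ids = snp_map.gene_to_snps.get(row.gene, frozenset())
        n_snps = len(snp_ids)
        n_indep = n_snps if pruned is None else len(snp_ids & pruned)
        n_hot = 0
        if row.chrom in hot_by_chrom:
            pos = hot_by_chrom[row.chrom]
            n_hot = int(
                np.searchsorted(pos, hi, "right") - np.searchsorted(pos, lo, "left")
            )
        cm = 0.0
        if row.chrom in gm_by_chrom:
            pos, cum = gm_by_chrom[row.chrom]
            cm = float(np.interp(hi, pos, cum) - np.interp(lo, pos, cum))
        rows.append(
            {
                "gene": row.gene,
                "size_kb": size_kb,
                "snps_per_kb": n_snps / size_kb,
                "indep_snps_per_kb": n_indep / size_kb,
                "hotspots_per_kb": n_hot / size_kb,
                "ld_units_per_kb": (
                    0.0 if ld_units is None else float(ld_units.get(row.gene, 0.0))
                ),
                "cM_per_kb": cm / size_kb,
            }
        )
    return pd.DataFrame(rows).set_index("gene")


# ---------------------------------------------------------------------------
# stepwise correction
# ---------------------------------------------------------------------------


def _stepwise_select(
    y: np.ndarray, X: pd.DataFrame, entry_p: float, removal_p: float
) -> list:
    """Forward selection with backward elimination on partial-F p-values.

    With a single added (or dropped) regressor the partial F test equals
    the squared-t test of its coefficient, so coefficient p-values from the
    OLS fit are used directly.
    """
    candidates = [c for c in X.columns if np.std(X[c].to_numpy()) > 0]
    selected: list = []
    for _ in range(2 * len(X.columns) + 1):  # loop guard
        changed = False
        remaining = [c for c in candidates if c not in selected]
        if remaining:
            best_c, best_p = None, np.inf
            for c in remaining:
                exog = sm.add_constant(X[selected + [c]])
                fit = sm.OLS(y, exog).fit()
                p = float(fit.pvalues[c])
                if p < best_p:
                    best_c, best_p = c, p
            if best_p < entry_p:
                selected.append(best_c)
                changed = True
        while selected:
            exog = sm.add_constant(X[selected])
            fit = sm.OLS(y, exog).fit()
            pvals = fit.pvalues.drop("const")
            worst = pvals.idxmax()
            if float(pvals[worst]) > removal_p:
                selected.remove(worst)
                changed = True
            else:
                break
        if not changed:
            break
    return selected


def correct_gene_scores(
    scores: Sequence[GeneScore] | pd.DataFrame,
    confounders: pd.DataFrame,
    entry_p: float = 0.05,
    removal_p: float = 0.10,
) -> pd.DataFrame:
    """Regress best-SNP Z-scores on selected confounders; return residual scores.

    Returns a DataFrame indexed by gene with columns ``raw_p``, ``z_raw``,
    ``z_corrected`` (unit-variance residual of z_raw on the stepwise-selected
    covariates; the standardized z_raw when nothing enters) and
    ``rank_fraction`` (the corrected score's quantile among all scored
    genes, 1 = most significant).  The selected covariates are recorded in
    ``DataFrame.attrs['selected_confounders']``.
    """
    if isinstance(scores, pd.DataFrame):
        df = scores.loc[:, ["gene", "best_p"]].copy()
    else:
        df = pd.DataFrame(
            {"gene": [s.gene_id for s in scores], "best_p": [s.best_p for s in scores]}
        )
    df = df.set_index("gene")
    X = confounders.reindex(df.index)
    if X.isna().any().any():
        missing = X.index[X.isna().any(axis=1)][:5].tolist()
        raise ValueError(f"confounders missing for genes: {missing}")
    n = len(df)
    if n < len(CONFOUNDER_COLUMNS) + 2:
        raise ValueError(
            f"{n} genes is too few for a {len(CONFOUNDER_COLUMNS)}-covariate regression"
        )
    if n < 20:
        log.warning("only %d genes; stepwise selection will be unstable", n)

    z_raw = stats.norm.isf(df["best_p"].to_numpy(float))
    selected = _stepwise_select(
        z_raw, X[list(CONFOUNDER_COLUMNS)], entry_p, removal_p
    )
    if selected:
        exog = sm.add_constant(X[selected])
        fit = sm.OLS(z_raw, exog).fit()
        resid = z_raw - fit.predict(exog)
    else:
        resid = z_raw - z_raw.mean()
    sd = resid.std(ddof=1)
    z_corr = resid / sd if sd > 0 else resid
    out = pd.DataFrame(
        {
            "raw_p": df["best_p"].to_numpy(float),
            "z_raw": z_raw,
            "z_corrected": z_corr,
            "rank_fraction": stats.rankdata(z_corr, method="average") / n,
        },
        index=df.index,
    )
    out.attrs["selected_confounders"] = list(selected)
    return out


# ---------------------------------------------------------------------------
# leading-edge permutation p
# ---------------------------------------------------------------------------


def leading_edge_p(
    corrected: pd.DataFrame,
    category_genes: Iterable[str],
    *,
    cutoff_quantile: float = DEFAULT_CUTOFF_QUANTILE,
    n_perm: int = DEFAULT_N_PERM,
    rng: np.random.Generator | int | None = None,
    proximity_filter: bool = False,
    genes: pd.DataFrame | None = None,
    gap_bp: int = DEFAULT_GAP_BP,
    category_id: str = "",
    name: str = "",
) -> GseaResult:
    """Permutation p for a category's leading-edge count.

    The leading edge is the set of category genes whose corrected scores
    sit at or above the ``cutoff_quantile`` rank fraction of all scored
    genes.  The observed count is compared to the counts in ``n_perm``
    uniform samples (without replacement) of equally many genes, with the
    add-one estimator.  With ``proximity_filter`` each cluster of category
    genes < 1 Mb apart contributes only its best-scoring member, mirroring
    the one-causal-gene-per-signal assumption.
    """
    rng = np.random.default_rng(rng)
    requested = set(category_genes)
    if len(requested) > len(corrected):
        raise ValueError("category larger than the scored gene universe")
    members = sorted(requested & set(corrected.index))
    if proximity_filter:
        if genes is None:
            raise ValueError("proximity_filter requires gene models")
        collapsed = collapse_proximal_genes(members, genes, gap_bp, category_id)
        members = sorted(
            max(ent, key=lambda g: (corrected.loc[g, "z_corrected"], g))
            for ent in collapsed.entities
        )
    size = len(members)
    n_genes = len(corrected)
    if size > n_genes:
        raise ValueError("category larger than the scored gene universe")
    leading = (corrected["rank_fraction"].to_numpy() >= cutoff_quantile)
    idx = corrected.index.get_indexer(members)
    observed = int(leading[idx].sum())
    if size == 0:
        return GseaResult(category_id, name or category_id, 0, 0, 0.0, 1.0)
    perm_counts = np.empty(n_perm, dtype=np.int64)
    for i in range(n_perm):
        sample = rng.choice(n_genes, size=size, replace=False)
        perm_counts[i] = leading[sample].sum()
    p = (1 + int(np.count_nonzero(perm_counts >= observed))) / (1 + n_perm)
    return GseaResult(
        category_id=category_id,
        name=name or category_id,
        n_genes=size,
        observed_leading=observed,
        expected_leading=float(perm_counts.mean()),
        p_nominal=p,
    )


def adjust_multiple(
    p_nominals: Sequence[float], method: str = "bonferroni"
) -> np.ndarray:
    """Adjust nominal p-values: ``bonferroni`` (min(1, m·p)) or ``bh_fdr``."""
    p = np.asarray(p_nominals, dtype=float)
    if p.size < 1:
        raise ValueError("need at least one p-value")
    if method == "bonferroni":
        return multipletests(p, method="bonferroni")[1]
    if method == "bh_fdr":
        return multipletests(p, method="fdr_bh")[1]
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# full per-study run
# ---------------------------------------------------------------------------


def run_magenta(
    snps: pd.DataFrame,
    genes: pd.DataFrame,
    gene_sets: GeneSetDb,
    ld: LdTable,
    *,
    study_id: str = "study",
    flank_bp: int = DEFAULT_FLANK_BP,
    r2_max: float = DEFAULT_R2_MAX,
    window_bp: int = DEFAULT_WINDOW_BP,
    cutoff_quantile: float = DEFAULT_CUTOFF_QUANTILE,
    n_perm: int = DEFAULT_N_PERM,
    entry_p: float = 0.05,
    removal_p: float = 0.10,
    proximity_filter: bool = False,
    gap_bp: int = DEFAULT_GAP_BP,
    hotspots: pd.DataFrame | None = None,
    genetic_map: pd.DataFrame | None = None,
    ld_units: Mapping[str, float] | None = None,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Run the GSEA-style analysis for one study.

    Returns a DataFrame (one row per category) with the leading-edge
    statistics, nominal permutation p, Bonferroni-adjusted p and BH false
    discovery rate.  The corrected gene scores are attached as
    ``DataFrame.attrs['gene_scores']``.
    """
    rng = np.random.default_rng(rng)
    snp_map = map_snps_to_genes(snps, genes, flank_bp)
    db = gene_sets.filter(snp_map.mapped_genes)
    pruned = ld_prune(snps, ld, r2_max, window_bp)
    scores = best_gene_pvalue(snp_map, snps)
    confounders = compute_confounders(
        genes, snp_map, pruned["snp"], hotspots, genetic_map, ld_units, flank_bp
    )
    corrected = correct_gene_scores(scores, confounders, entry_p, removal_p)

    results = []
    for cid in sorted(db.categories):
        res = leading_edge_p(
            corrected,
            db.categories[cid],
            cutoff_quantile=cutoff_quantile,
            n_perm=n_perm,
            rng=rng,
            proximity_filter=proximity_filter,
            genes=genes,
            gap_bp=gap_bp,
            category_id=cid,
            name=db.name(cid),
        )
        results.append(res)
    p_nominal = [r.p_nominal for r in results]
    bonf = adjust_multiple(p_nominal, "bonferroni")
    fdr = adjust_multiple(p_nominal, "bh_fdr")
    rows = []
    for r, pb, q in zip(results, bonf, fdr):
        r.p_bonferroni = float(pb)
        r.fdr = float(q)
        rows.append(
            {
                "category": r.category_id,
                "name": r.name,
                "n_genes": r.n_genes,
                "observed_leading": r.observed_leading,
                "expected_leading": r.expected_leading,
                "p_nominal": r.p_nominal,
                "p_bonferroni": r.p_bonferroni,
                "fdr": r.fdr,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["gene_scores"] = corrected
    out.attrs["study_id"] = study_id
    return out
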