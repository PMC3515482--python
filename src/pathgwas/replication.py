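"""Multi-study layer: overlap of enriched categories, its permutation
significance, third-study replication, weighted-Z combination and category
clustering.

The replication design mirrors a two-stage strategy: categories enriched in
both exploratory studies are identified, the chance level of that overlap is
assessed by rerunning the bootstrap of study A restricted to the categories
enriched in study B, surviving categories are checked in a third study at
alpha = 0.05, and per-study enrichment p-values are pooled with the
weighted Z-score (Stouffer) method using sqrt(sample size) weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .aligator import AligatorResult, bootstrap_pseudo_p
from .io import StudyMeta

log = logging.getLogger(__name__)


@dataclass
class StudyEnrichment:
    """One study's per-category enrichment results plus its metadata.

    ``pvalues`` maps category id to the study's enrichment p-value
    (empirical p for the overrepresentation method, nominal p for GSEA).
    """

    study_id: str
    meta: StudyMeta
    pvalues: Mapping[str, float]

    def significant(self, threshold: float) -> frozenset:
        return frozenset(c for c, p in self.pvalues.items() if p < threshold)


@dataclass(frozen=True)
class CommonCategoryReport:
    """Overlap of enriched categories between two studies at one threshold."""

    snp_threshold: float
    category_threshold: float
    common_ids: frozenset
    p_overlap: float

    @property
    def n_common(self) -> int:
        return len(self.common_ids)


@dataclass(frozen=True)
class CombinedResult:
    """Weighted-Z pooled enrichment evidence for one category."""

    category_id: str
    per_study_p: tuple
    weights: tuple
    z_combined: float
    p_combined: float


def common_enriched(
    a: StudyEnrichment, b: StudyEnrichment, category_threshold: float
) -> frozenset:
    """Categories with enrichment p < threshold in both studies."""
    if set(a.pvalues) != set(b.pvalues):
        raise ValueError(
            "studies were scored against different category databases"
        )
    return a.significant(category_threshold) & b.significant(category_threshold)


def overlap_significance(
    a_result: AligatorResult,
    enriched_in_b: Iterable[str],
    category_threshold: float,
    n_boot: int = 1000,
    subsample: int = 5000,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Chance probability of the observed two-study overlap.

    Reruns study A's bootstrap restricted to the categories enriched in
    study B: the observed statistic is how many of those categories study A
    enriches below ``category_threshold``; the null counts the same
    statistic in pseudo-studies assembled from study A's replicate
    ensemble.  Add-one corrected.
    """
    rng = np.random.default_rng(rng)
    restricted = sorted(set(enriched_in_b))
    if not restricted:
        log.warning("no categories enriched in the conditioning study")
        return 1.0
    col = {c: i for i, c in enumerate(a_result.category_ids)}
    missing = [c for c in restricted if c not in col]
    if missing:
        raise ValueError(f"categories not scored in study A: {missing[:5]}")
    cols = [col[c] for c in restricted]
    counts = a_result.counts[:, cols]
    n_common = sum(
        1
        for c in restricted
        if a_result.results[c].p_empirical < category_threshold
    )
    subsample = min(subsample, counts.shape[0])
    pseudo_p = bootstrap_pseudo_p(counts, n_boot, subsample, rng)
    null_counts = (pseudo_p < category_threshold).sum(axis=1)
    return (1 + int(np.count_nonzero(null_counts >= n_common))) / (1 + n_boot)


def replicate_in_third(
    common: Iterable[str], c: StudyEnrichment, alpha: float = 0.05
) -> frozenset:
    """Subset of the two-study common categories with p < alpha in study C."""
    common = frozenset(common)
    missing = common - set(c.pvalues)
    if missing:
        raise ValueError(
            f"categories absent from study {c.study_id}: {sorted(missing)[:5]}"
        )
    return frozenset(cid for cid in common if c.pvalues[cid] < alpha)


def combine_pvalues_weighted_z(
    per_study_p: Sequence[float],
    weights: Sequence[float] | None = None,
    category_id: str = "",
) -> CombinedResult:
    """Weighted Z-score (Stouffer) combination of one-sided p-values.

    z_i = Φ⁻¹(1 − p_i);  Z = Σ w_i z_i / sqrt(Σ w_i²);  p = 1 − Φ(Z).
    Weights default to 1; the recommended choice is sqrt(study sample
    size).  The combination is invariant to rescaling all weights.
    """
    p = np.asarray(per_study_p, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("p-values must lie strictly inside (0, 1)")
    w = np.ones_like(p) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != p.shape or np.any(w <= 0):
        raise ValueError("weights must be positive, one per study")
    z = stats.norm.isf(p)
    z_comb = float(w @ z / np.sqrt(w @ w))
    return CombinedResult(
        category_id=category_id,
        per_study_p=tuple(p),
        weights=tuple(w),
        z_combined=z_comb,
        p_combined=float(stats.norm.sf(z_comb)),
    )


def combine_studies(
    studies: Sequence[StudyEnrichment],
    categories: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Weighted-Z combination for every category across studies.

    Weights are sqrt(n_subjects) per study.  Returns a DataFrame with one
    row per category: the per-study p-values, Z and combined p.
    """
    if not studies:
        raise ValueError("no studies to combine")
    cats = sorted(categories) if categories is not None else sorted(
        studies[0].pvalues
    )
    weights = [np.sqrt(s.meta.n_subjects) for s in studies]
    rows = []
    for cid in cats:
        ps = [s.pvalues[cid] for s in studies]
        row = {"category": cid}
        for s, p in zip(studies, ps):
            row[f"p_{s.study_id}"] = p
        if all(0.0 < p < 1.0 for p in ps):
            res = combine_pvalues_weighted_z(ps, weights, cid)
            row["z_combined"] = res.z_combined
            row["p_combined"] = res.p_combined
        else:
            # an empirical p at its ceiling of 1 has an unbounded Z;
            # the combination is left undefined for such rows
            row["z_combined"] = np.nan
            row["p_combined"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def cluster_categories(
    gene_sets: Mapping[str, frozenset],
    metric: str = "jaccard",
    cut_height: float | None = None,
) -> tuple[list, np.ndarray, np.ndarray | None]:
    """Single-linkage clustering of categories by gene-set similarity.

    Pairwise similarity is the Jaccard index (or the overlap coefficient
    with ``metric='overlap'``); distance is 1 − similarity.  Returns the
    ordered category ids, the scipy linkage matrix of the single-linkage
    (nearest-neighbor) agglomeration, and — when ``cut_height`` is given —
    flat cluster labels from cutting the dendrogram at that distance.
    """
    ids = sorted(gene_sets)
    if len(ids) < 2:
        raise ValueError("need at least two categories to cluster")
    n = len(ids)
    dist = np.zeros((n, n))
    for i in range(n):
        gi = gene_sets[ids[i]]
        for j in range(i + 1, n):
            gj = gene_sets[ids[j]]
            inter = len(gi & gj)
            if metric == "jaccard":
                denom = len(gi | gj)
            elif metric == "overlap":
                denom = min(len(gi), len(gj))
            else:
                raise ValueError(f"unknown metric {metric!r}")
            sim = inter / denom if denom else 0.0
            dist[i, j] = dist[j, i] = 1.0 - sim
    Z = linkage(squareform(dist, checks=False), method="single")
    labels = None
    if cut_height is not None:
        labels = fcluster(Z, t=cut_height, criterion="distance")
    return ids, Z, labels


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance threshold alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m
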