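"""Independent brute-force oracles used across test modules.

Every oracle here re-derives the expected result by a different route than
the library implementation (all-pairs scans, exhaustive enumeration, graph
components), so agreement is evidence, not tautology.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd


def brute_force_snp_gene_map(snps: pd.DataFrame, genes: pd.DataFrame, flank: int):
    """O(S·G) all-pairs interval check."""
    out = {}
    for s in snps.itertuples():
        hits = set()
        for g in genes.itertuples():
            if s.chrom == g.chrom and g.start - flank <= s.pos <= g.end + flank:
                hits.add(g.gene)
        out[s.snp] = frozenset(hits)
    return out


def greedy_prune_oracle(snps: pd.DataFrame, r2_lookup, r2_max, window_bp):
    """Independent greedy-by-significance pruning using an all-pairs scan.

    ``r2_lookup(a, b)`` returns the pairwise r².  Visits SNPs by ascending
    (p, pos, snp) and keeps a SNP unless some kept SNP on the same
    chromosome within the window has r² above the cutoff.
    """
    rows = sorted(snps.itertuples(), key=lambda r: (r.p, r.pos, r.snp))
    kept = []
    for r in rows:
        conflict = any(
            k.chrom == r.chrom
            and abs(k.pos - r.pos) <= window_bp
            and r2_lookup(k.snp, r.snp) > r2_max
            for k in kept
        )
        if not conflict:
            kept.append(r)
    return {k.snp for k in kept}


def exhaustive_replicate_distribution(snp_genes, n, n_genes):
    """Exact distribution over replicate gene lists via permutation
    enumeration.

    Enumerates every ordering of the SNP pool, applies the
    accumulate-with-overshoot-rejection rule, and returns a dict mapping
    each reachable gene list (as a frozenset of indices) to its
    probability.  Feasible for <= 8 SNPs.
    """
    counts: dict[frozenset, int] = {}
    total = 0
    for perm in itertools.permutations(range(len(snp_genes))):
        got: set[int] = set()
        for si in perm:
            gs = set(snp_genes[si])
            new = gs - got
            if len(got) + len(new) > n:
                continue
            got |= new
            if len(got) == n:
                break
        if len(got) == n:
            key = frozenset(got)
            counts[key] = counts.get(key, 0) + 1
            total += 1
    return {k: v / total for k, v in counts.items()}


def exact_category_p(dist, category_idx, observed):
    """P(list count >= observed) under an exact replicate-list distribution."""
    cat = set(category_idx)
    return sum(p for lst, p in dist.items() if len(lst & cat) >= observed)
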