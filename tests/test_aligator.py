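import numpy as np
import pandas as pd
import pytest
from scipy import stats

from _helpers import (
    exact_category_p,
    exhaustive_replicate_distribution,
)
from conftest import make_genes, make_snps
from pathgwas.aligator import (
    build_replicate_ensemble,
    category_empirical_p,
    empirical_p,
    excess_of_enrichment,
    run_aligator,
    sample_replicate_list,
    select_significant_genes,
    studywide_bootstrap,
)
from pathgwas.io import GeneSetDb, LdTable
from pathgwas.mapping import map_snps_to_genes


def _single_gene_universe(n_genes, p_values=None):
    """One SNP per gene, no LD: the simplest taggable universe."""
    genes = make_genes(
        [(f"G{i}", "chr1", 1 + i * 3_000_000, 1000 + i * 3_000_000) for i in range(n_genes)]
    )
    ps = p_values if p_values is not None else [0.5] * n_genes
    snps = make_snps(
        [(f"rs{i}", "chr1", 500 + i * 3_000_000, ps[i]) for i in range(n_genes)]
    )
    return genes, snps


class TestSelectSignificantGenes:
    def test_threshold_is_strict(self):
        genes, snps = _single_gene_universe(3, [0.0009, 0.001, 0.04])
        m = map_snps_to_genes(snps, genes)
        sel = select_significant_genes(m, snps, 0.001)
        assert sel.gene_ids == frozenset({"G0"})

    def test_multi_gene_snp_contributes_all_genes(self):
        genes = make_genes(
            [("G1", "chr1", 100_000, 110_000), ("G2", "chr1", 112_000, 120_000)]
        )
        snps = make_snps([("rs1", "chr1", 111_000, 1e-4)])
        m = map_snps_to_genes(snps, genes)
        sel = select_significant_genes(m, snps, 0.001)
        assert sel.gene_ids == frozenset({"G1", "G2"})
        assert sel.n == 2

    def test_matches_brute_force_filter(self, small_dataset):
        snps = small_dataset.studies["STUDY1"]
        m = map_snps_to_genes(snps, small_dataset.genes)
        sel = select_significant_genes(m, snps, 0.05)
        expected = set()
        for row in snps.itertuples():
            if row.p < 0.05:
                expected |= m.snp_to_genes[row.snp]
        assert sel.gene_ids == frozenset(expected)


class TestSampleReplicateList:
    def test_saturation_returns_full_universe(self, rng):
        snp_genes = [np.array([i]) for i in range(6)]
        lst = sample_replicate_list(snp_genes, 6, 6, rng)
        assert list(lst) == list(range(6))

    def test_overshooting_multigene_snp_always_rejected(self, rng):
        # one SNP tags 2 genes; at n=1 that draw must always be rejected
        snp_genes = [np.array([0, 1]), np.array([2])]
        for _ in range(200):
            lst = sample_replicate_list(snp_genes, 1, 3, rng)
            assert list(lst) == [2]

    def test_non_tagging_snps_consume_draws_harmlessly(self, rng):
        snp_genes = [np.array([], dtype=np.int64), np.array([0]), np.array([1])]
        lst = sample_replicate_list(snp_genes, 2, 2, rng)
        assert list(lst) == [0, 1]

    def test_unreachable_n_raises(self, rng):
        with pytest.raises(ValueError):
            sample_replicate_list([np.array([0])], 2, 1, rng)

    def test_single_gene_draws_uniform(self, rng):
        # n=1 over 8 single-gene SNPs: draw frequencies must pass a
        # chi-square goodness-of-fit test against uniform
        snp_genes = [np.array([i]) for i in range(8)]
        draws = [
            sample_replicate_list(snp_genes, 1, 8, rng)[0] for _ in range(10_000)
        ]
        observed = np.bincount(draws, minlength=8)
        chi2 = ((observed - 1250.0) ** 2 / 1250.0).sum()
        assert stats.chi2.sf(chi2, df=7) > 0.001


class TestCategoryEmpiricalP:
    def _ensemble(self, n_genes, n, R, seed=7):
        genes, snps = _single_gene_universe(n_genes)
        m = map_snps_to_genes(snps, genes)
        return build_replicate_ensemble(m, n, R, np.random.default_rng(seed))

    def test_observed_zero_gives_p_one(self):
        ens = self._ensemble(6, 2, 200)
        from pathgwas.aligator import SignificantGeneList

        sel = SignificantGeneList(0.05, frozenset())
        res = category_empirical_p(sel, {"G0", "G1"}, ens, "c")
        assert res.p_empirical == 1.0

    def test_unbeatable_observation_hits_floor(self):
        from pathgwas.aligator import SignificantGeneList

        # category = {G0, G1}; replicates of size 1 can contain at most one
        ens = self._ensemble(6, 1, 400)
        sel = SignificantGeneList(0.05, frozenset({"G0", "G1"}))
        res = category_empirical_p(sel, {"G0", "G1"}, ens, "c")
        assert res.observed == 2
        assert res.p_empirical == pytest.approx(1 / 401)

    def test_p_within_floor_and_one(self, small_dataset):
        snps = small_dataset.studies["STUDY1"]
        res = run_aligator(
            snps,
            small_dataset.genes,
            small_dataset.gene_sets,
            small_dataset.ld,
            snp_threshold=0.05,
            n_replicates=300,
            n_boot=50,
            subsample=100,
            rng=3,
        )
        for r in res.results.values():
            assert 1 / 301 <= r.p_empirical <= 1.0

    def test_matches_exhaustive_enumeration_oracle(self):
        # 5 single-gene SNPs + 1 two-gene SNP, n = 3: the exact list
        # distribution is enumerable over all 6! SNP orderings
        genes = make_genes(
            [(f"G{i}", "chr1", 1 + i * 3_000_000, 1000 + i * 3_000_000) for i in range(5)]
            + [("G5", "chr1", 1500 + 4 * 3_000_000, 2500 + 4 * 3_000_000)]
        )
        snps = make_snps(
            [(f"rs{i}", "chr1", 500 + i * 3_000_000, 0.5) for i in range(4)]
            + [("rs_shared", "chr1", 1800 + 4 * 3_000_000, 0.5)]
        )
        m = map_snps_to_genes(snps, genes)
        universe = sorted(m.mapped_genes)
        gidx = {g: i for i, g in enumerate(universe)}
        snp_genes = [
            np.array(sorted(gidx[g] for g in m.snp_to_genes[s]))
            for s in sorted(m.snp_to_genes)
        ]
        dist = exhaustive_replicate_distribution(snp_genes, 3, len(universe))
        category = [gidx[g] for g in ("G0", "G4", "G5")]
        for observed in (1, 2, 3):
            exact = exact_category_p(dist, category, observed)
            ens = build_replicate_ensemble(m, 3, 5000, np.random.default_rng(11))
            memb = np.zeros(len(universe), dtype=bool)
            memb[category] = True
            counts = np.array([memb[lst].sum() for lst in ens.lists])
            mc = empirical_p(observed, counts)
            se = np.sqrt(exact * (1 - exact) / 5000)
            assert abs(mc - exact) <= 3 * se + 1 / 5001


class TestStudywideAndExcess:
    def _toy_counts(self, seed=5, R=400, C=3):
        rng = np.random.default_rng(seed)
        return rng.binomial(5, 0.3, size=(R, C))

    def test_category_at_p_one_stays_at_one(self):
        counts = self._toy_counts()
        ps = {"a": 1.0, "b": 0.2, "c": 0.5}
        sw = studywide_bootstrap(
            ps, counts, ["a", "b", "c"], n_boot=200, subsample=200,
            rng=np.random.default_rng(1),
        )
        assert sw["a"] == 1.0

    def test_studywide_never_smaller_than_empirical(self, small_dataset):
        res = run_aligator(
            small_dataset.studies["STUDY1"],
            small_dataset.genes,
            small_dataset.gene_sets,
            small_dataset.ld,
            snp_threshold=0.05,
            n_replicates=400,
            n_boot=150,
            subsample=200,
            rng=9,
        )
        for r in res.results.values():
            # min over categories is stochastically smaller than any single
            # category's p, so selection can only inflate significance
            assert r.p_studywide >= r.p_empirical - 0.05

    def test_single_category_studywide_tracks_empirical(self):
        # with one category there is no selection effect, so the
        # study-wide p must track the empirical p; because counts are
        # discrete, pseudo-study p-values at the observed count's own atom
        # fall on either side of p_empirical, so the study-wide estimate is
        # bracketed by the atom-exclusive and atom-inclusive tails
        genes, snps = _single_gene_universe(8, [0.0005] + [0.6] * 7)
        db = GeneSetDb({"only": frozenset({"G0", "G1", "G2"})}, {"only": "only"})
        res = run_aligator(
            snps, genes, db, LdTable(), snp_threshold=0.05,
            n_replicates=2000, n_boot=400, subsample=1000, rng=21,
        )
        r = res.results["only"]
        exclusive = (1 + np.count_nonzero(res.counts[:, 0] > r.observed)) / (
            1 + res.counts.shape[0]
        )
        assert exclusive - 0.05 <= r.p_studywide <= r.p_empirical + 0.05

    def test_no_significant_categories_excess_near_one(self):
        counts = self._toy_counts()
        ps = {"a": 1.0, "b": 0.9, "c": 0.8}
        df = excess_of_enrichment(
            ps, counts, ["a", "b", "c"], n_boot=200, subsample=200,
            rng=np.random.default_rng(2),
        )
        assert (df["n_enriched"] == 0).all()
        assert (df["p_excess"] > 0.9).all()

    def test_enriched_count_monotone_in_threshold(self, small_dataset):
        res = run_aligator(
            small_dataset.studies["STUDY1"],
            small_dataset.genes,
            small_dataset.gene_sets,
            small_dataset.ld,
            snp_threshold=0.05,
            n_replicates=300,
            n_boot=100,
            subsample=150,
            rng=13,
        )
        counts = res.excess.sort_values("category_threshold")["n_enriched"]
        assert counts.is_monotonic_increasing


class TestCollapsedRun:
    def test_no_proximal_pairs_equals_uncollapsed(self):
        genes, snps = _single_gene_universe(10, [0.001, 0.002] + [0.6] * 8)
        db = GeneSetDb(
            {"c1": frozenset({"G0", "G3", "G7"}), "c2": frozenset({"G1", "G5", "G9"})},
        )
        kw = dict(
            snp_threshold=0.05, n_replicates=500, n_boot=100, subsample=200,
        )
        plain = run_aligator(snps, genes, db, LdTable(), collapse=False, rng=4, **kw)
        collapsed = run_aligator(snps, genes, db, LdTable(), collapse=True, rng=4, **kw)
        for cid in db:
            a, b = plain.results[cid], collapsed.results[cid]
            assert (a.observed, a.p_empirical) == (b.observed, b.p_empirical)

    def test_single_entity_category_counts_at_most_once(self):
        # three genes within 1 Mb of each other form one entity
        genes = make_genes(
            [
                ("G0", "chr1", 1_000_000, 1_010_000),
                ("G1", "chr1", 1_400_000, 1_410_000),
                ("G2", "chr1", 1_800_000, 1_810_000),
                ("G3", "chr2", 1_000_000, 1_010_000),
                ("G4", "chr2", 5_000_000, 5_010_000),
            ]
        )
        snps = make_snps(
            [
                ("rs0", "chr1", 1_005_000, 1e-4),
                ("rs1", "chr1", 1_405_000, 1e-4),
                ("rs2", "chr1", 1_805_000, 0.5),
                ("rs3", "chr2", 1_005_000, 0.5),
                ("rs4", "chr2", 5_005_000, 0.5),
            ]
        )
        db = GeneSetDb({"cluster": frozenset({"G0", "G1", "G2"})})
        res = run_aligator(
            snps, genes, db, LdTable(), snp_threshold=0.05, collapse=True,
            n_replicates=300, n_boot=50, subsample=100, rng=6,
        )
        r = res.results["cluster"]
        assert r.observed == 1  # two significant genes, one entity
        assert r.expected <= 1.0


class TestDeterminism:
    def test_same_seed_identical_results(self, small_dataset):
        kw = dict(
            snp_threshold=0.05, n_replicates=200, n_boot=60, subsample=100,
        )
        a = run_aligator(
            small_dataset.studies["STUDY1"], small_dataset.genes,
            small_dataset.gene_sets, small_dataset.ld, rng=123, **kw,
        )
        b = run_aligator(
            small_dataset.studies["STUDY1"], small_dataset.genes,
            small_dataset.gene_sets, small_dataset.ld, rng=123, **kw,
        )
        for cid in a.results:
            ra, rb = a.results[cid], b.results[cid]
            assert (ra.observed, ra.expected, ra.p_empirical, ra.p_studywide) == (
                rb.observed, rb.expected, rb.p_empirical, rb.p_studywide,
            )
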