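import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_genes, make_snps
from pathgwas.magenta import (
    CONFOUNDER_COLUMNS,
    adjust_multiple,
    compute_confounders,
    correct_gene_scores,
    leading_edge_p,
    run_magenta,
)
from pathgwas.mapping import GeneScore, map_snps_to_genes


def _uniform_scores(n, rng):
    return [GeneScore(f"G{i:04d}", float(rng.uniform()), f"rs{i}", 1) for i in range(n)]


def _neutral_confounders(gene_ids, rng=None):
    n = len(gene_ids)
    rng = rng or np.random.default_rng(0)
    data = {c: rng.uniform(0.1, 1.0, n) for c in CONFOUNDER_COLUMNS}
    return pd.DataFrame(data, index=pd.Index(gene_ids, name="gene"))


class TestComputeConfounders:
    def test_window_size_and_snp_density(self):
        genes = make_genes([("G1", "chr1", 100_001, 110_000)])  # 10 kb span
        snps = make_snps(
            [(f"rs{i}", "chr1", 101_000 + i, 0.5) for i in range(5)]
        )
        m = map_snps_to_genes(snps, genes, flank_bp=20_000)
        conf = compute_confounders(genes, m, flank_bp=20_000)
        assert conf.loc["G1", "size_kb"] == pytest.approx(50.0)
        assert conf.loc["G1", "snps_per_kb"] == pytest.approx(0.1)

    def test_absent_tracks_default_to_zero(self):
        genes = make_genes([("G1", "chr1", 100_001, 110_000)])
        snps = make_snps([("rs1", "chr1", 101_000, 0.5)])
        m = map_snps_to_genes(snps, genes)
        conf = compute_confounders(genes, m)
        assert conf.loc["G1", "cM_per_kb"] == 0.0
        assert conf.loc["G1", "hotspots_per_kb"] == 0.0
        assert conf.loc["G1", "ld_units_per_kb"] == 0.0

    def test_hotspot_and_genetic_map_densities(self):
        genes = make_genes([("G1", "chr1", 100_001, 110_000)])
        snps = make_snps([("rs1", "chr1", 101_000, 0.5)])
        m = map_snps_to_genes(snps, genes, flank_bp=20_000)
        hotspots = pd.DataFrame(
            {"chrom": ["chr1"] * 3, "pos": [85_000, 100_500, 200_000]}
        )
        gmap = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "pos": [0, 1_000_000], "cM": [0.0, 1.0]}
        )
        conf = compute_confounders(
            genes, m, hotspots=hotspots, genetic_map=gmap, flank_bp=20_000
        )
        # window [80001, 130000]: two hotspots inside
        assert conf.loc["G1", "hotspots_per_kb"] == pytest.approx(2 / 50.0)
        # 1 cM/Mb map: the 49,999 bp window span covers 0.049999 cM
        assert conf.loc["G1", "cM_per_kb"] == pytest.approx(0.049999 / 50.0)

    def test_independent_snp_density_uses_pruned_set(self):
        genes = make_genes([("G1", "chr1", 100_001, 110_000)])
        snps = make_snps(
            [("rs1", "chr1", 101_000, 0.5), ("rs2", "chr1", 102_000, 0.5)]
        )
        m = map_snps_to_genes(snps, genes)
        conf = compute_confounders(genes, m, pruned_snp_ids=["rs1"])
        assert conf.loc["G1", "indep_snps_per_kb"] == pytest.approx(1 / 50.0)
        assert conf.loc["G1", "snps_per_kb"] == pytest.approx(2 / 50.0)


class TestCorrectGeneScores:
    def test_constant_confounders_select_nothing(self, rng):
        scores = _uniform_scores(100, rng)
        conf = pd.DataFrame(
            {c: np.ones(100) for c in CONFOUNDER_COLUMNS},
            index=[s.gene_id for s in scores],
        )
        out = correct_gene_scores(scores, conf)
        assert out.attrs["selected_confounders"] == []
        z = stats.norm.isf(out["raw_p"])
        expected = (z - z.mean()) / (z - z.mean()).std(ddof=1)
        np.testing.assert_allclose(out["z_corrected"], expected, atol=1e-10)

    def test_planted_covariate_recovered_and_removed(self):
        # z_raw built as 2*size_kb + noise: stepwise must select size_kb
        # and leave residuals uncorrelated with it
        rng = np.random.default_rng(7)
        n = 2000
        gene_ids = [f"G{i:05d}" for i in range(n)]
        conf = _neutral_confounders(gene_ids, rng)
        conf["size_kb"] = rng.uniform(0.5, 15, n)  # keeps norm.sf(z) > 0
        z = 2.0 * conf["size_kb"].to_numpy() + rng.normal(size=n)
        scores = pd.DataFrame({"gene": gene_ids, "best_p": stats.norm.sf(z)})
        out = correct_gene_scores(scores, conf)
        assert "size_kb" in out.attrs["selected_confounders"]
        r = np.corrcoef(out["z_corrected"], conf["size_kb"])[0, 1]
        assert abs(r) < 0.01

    def test_joint_relabeling_preserves_score_multiset(self, rng):
        scores = _uniform_scores(60, rng)
        conf = _neutral_confounders([s.gene_id for s in scores], rng)
        out = correct_gene_scores(scores, conf)
        perm = rng.permutation(60)
        scores_p = [scores[i] for i in perm]
        conf_p = conf.iloc[perm]
        out_p = correct_gene_scores(scores_p, conf_p)
        np.testing.assert_allclose(
            np.sort(out["z_corrected"]), np.sort(out_p["z_corrected"]), atol=1e-10
        )

    def test_too_few_genes_rejected(self, rng):
        scores = _uniform_scores(5, rng)
        conf = _neutral_confounders([s.gene_id for s in scores])
        with pytest.raises(ValueError, match="too few"):
            correct_gene_scores(scores, conf)


def _ranked_universe(n):
    """Corrected-score frame with gene i at rank fraction (i+1)/n."""
    genes = [f"G{i:03d}" for i in range(n)]
    z = np.linspace(-3, 3, n)
    return pd.DataFrame(
        {
            "raw_p": stats.norm.sf(z),
            "z_raw": z,
            "z_corrected": z,
            "rank_fraction": stats.rankdata(z) / n,
        },
        index=pd.Index(genes, name="gene"),
    )


class TestLeadingEdgeP:
    def test_fully_leading_category_hits_floor(self, rng):
        scores = _ranked_universe(200)
        top = list(scores.index[-10:])  # all within the top 5%
        res = leading_edge_p(scores, top, n_perm=500, rng=rng)
        assert res.observed_leading == 10
        assert res.p_nominal == pytest.approx(1 / 501)

    def test_zero_leading_genes_gives_p_one(self, rng):
        scores = _ranked_universe(200)
        bottom = list(scores.index[:10])
        res = leading_edge_p(scores, bottom, n_perm=500, rng=rng)
        assert res.observed_leading == 0
        assert res.p_nominal == 1.0

    def test_category_exceeding_universe_rejected(self, rng):
        scores = _ranked_universe(20)
        with pytest.raises(ValueError):
            leading_edge_p(scores, [f"X{i}" for i in range(30)], rng=rng)

    def test_matches_exhaustive_hypergeometric_oracle(self):
        # 20-gene universe, category of 4: every C(20,4) sample is
        # enumerable, giving the exact null tail for each observed count
        scores = _ranked_universe(20)
        leading = (scores["rank_fraction"] >= 0.95).to_numpy()
        category = list(scores.index[-3:]) + [scores.index[0]]
        idx = scores.index.get_indexer(category)
        observed = int(leading[idx].sum())
        tail = 0.0
        total = 0
        for combo in itertools.combinations(range(20), 4):
            total += 1
            if leading[list(combo)].sum() >= observed:
                tail += 1
        exact = tail / total
        res = leading_edge_p(
            scores, category, n_perm=4000, rng=np.random.default_rng(3)
        )
        se = np.sqrt(exact * (1 - exact) / 4000)
        assert abs(res.p_nominal - exact) <= 3 * se + 1 / 4001

    def test_invariant_to_monotone_transform_of_scores(self):
        scores = _ranked_universe(100)
        transformed = scores.copy()
        transformed["z_corrected"] = np.exp(scores["z_corrected"])
        transformed["rank_fraction"] = (
            stats.rankdata(transformed["z_corrected"]) / 100
        )
        cat = list(scores.index[-8:]) + list(scores.index[:2])
        a = leading_edge_p(scores, cat, n_perm=300, rng=np.random.default_rng(5))
        b = leading_edge_p(
            transformed, cat, n_perm=300, rng=np.random.default_rng(5)
        )
        assert (a.observed_leading, a.p_nominal) == (b.observed_leading, b.p_nominal)

    def test_proximity_filter_keeps_best_gene_per_cluster(self, rng):
        scores = _ranked_universe(6)
        genes = make_genes(
            [
                ("G000", "chr1", 1_000_000, 1_010_000),
                ("G005", "chr1", 1_200_000, 1_210_000),  # clusters with G000
                ("G002", "chr2", 1_000_000, 1_010_000),
            ]
        )
        res = leading_edge_p(
            scores,
            ["G000", "G005", "G002"],
            proximity_filter=True,
            genes=genes,
            n_perm=100,
            rng=rng,
        )
        # cluster (G000, G005) contributes only its best scorer: size 2
        assert res.n_genes == 2


class TestAdjustMultiple:
    def test_bonferroni_threshold_of_the_multi_study_screen(self):
        # 8179 categories at alpha 0.05: per-test threshold 6.11e-6, i.e. a
        # nominal p at that level is adjusted to ~alpha
        m = 8179
        p = np.zeros(m)
        p[0] = 6.11e-6
        p[1:] = 0.5
        adj = adjust_multiple(p, "bonferroni")
        assert adj[0] == pytest.approx(0.05, rel=1e-3)

    def test_single_test_identity(self):
        assert adjust_multiple([0.037], "bonferroni")[0] == pytest.approx(0.037)
        assert adjust_multiple([0.037], "bh_fdr")[0] == pytest.approx(0.037)

    def test_bh_step_up_hand_computed(self):
        adj = adjust_multiple([0.01, 0.02, 0.03, 0.04], "bh_fdr")
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])


class TestRunMagenta:
    def test_planted_category_most_significant(self, small_dataset):
        tab = run_magenta(
            small_dataset.studies["STUDY1"],
            small_dataset.genes,
            small_dataset.gene_sets,
            small_dataset.ld,
            n_perm=800,
            rng=17,
        )
        planted = small_dataset.truth.planted_category_ids
        best = tab.sort_values("p_nominal").iloc[0]["category"]
        assert best in planted

    def test_null_pvalues_not_enriched(self):
        # no planted signal: the fraction of categories nominally below
        # 0.05 stays near its expectation
        from pathgwas.simulate import SimulationConfig, simulate_dataset

        cfg = SimulationConfig(
            n_genes=300, n_categories=60, n_planted=0, n_studies=1,
            category_size=(20, 60), seed=99,
        )
        ds = simulate_dataset(cfg)
        tab = run_magenta(
            ds.studies["STUDY1"], ds.genes, ds.gene_sets, ds.ld,
            n_perm=600, rng=23,
        )
        frac = (tab["p_nominal"] < 0.05).mean()
        assert frac <= 0.12
        assert tab["p_nominal"].median() > 0.25
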