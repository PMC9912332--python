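"""Single-cell readouts: percent-positive, rank-sum DE, BH, hypergeometric ORA."""

import itertools
import math

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from statsmodels.stats.proportion import proportion_confint

from lnpscreen.sc import (
    differential_expression,
    ora_hypergeometric,
    percent_positive,
    read_gene_sets,
    top_upregulated,
)
from lnpscreen.synth import ScSimConfig, simulate_sc_matrix


def tiny_adata(X, clusters, groups, genes=None):
    genes = genes or [f"g{i}" for i in range(np.asarray(X).shape[1])]
    a = ad.AnnData(
        X=sp.csr_matrix(np.asarray(X)),
        obs=pd.DataFrame({"cluster": clusters, "group": groups},
                         index=[f"c{i}" for i in range(len(clusters))]),
        var=pd.DataFrame(index=pd.Index(genes, name="gene_id")),
    )
    return a


class TestPercentPositive:
    def test_direct_count(self):
        X = [[0, 1], [0, 2], [0, 5], [0, 0]]
        a = tiny_adata(X, ["k"] * 4, ["g"] * 4)
        out = percent_positive(a, "g1")
        assert out.loc[0, "percent"] == 75.0 and out.loc[0, "n_cells"] == 4

    def test_gene_absent_from_all_cells_is_zero_everywhere(self):
        adata, _ = simulate_sc_matrix(
            ScSimConfig(n_genes=30, n_cells_per_cluster=10, avhh_capture_prob={},
                        seed=1)
        )
        out = percent_positive(adata)  # defaults to the aVHH pseudogene
        assert (out["percent"] == 0).all()

    def test_unknown_gene_named_in_error(self):
        a = tiny_adata([[1]], ["k"], ["g"])
        with pytest.raises(KeyError, match="nope"):
            percent_positive(a, "nope")

    def test_zero_cell_strata_absent_not_zero(self):
        X = [[1], [0]]
        a = tiny_adata(X, ["k1", "k2"], ["gA", "gA"])
        out = percent_positive(a, "g0")
        # cluster/group combinations with no cells do not appear as 0% rows
        assert len(out) == 2
        assert set(zip(out["cluster"], out["group"])) == {("k1", "gA"), ("k2", "gA")}

    def test_invariant_to_cell_and_gene_order(self):
        adata, _ = simulate_sc_matrix(
            ScSimConfig(n_genes=20, n_cells_per_cluster=15, seed=2)
        )
        rng = np.random.default_rng(3)
        shuffled = adata[rng.permutation(adata.n_obs),
                         rng.permutation(adata.n_vars)].copy()
        shuffled.uns["avhh_gene"] = "aVHH"
        a = percent_positive(adata).sort_values(["cluster", "group"]).reset_index(drop=True)
        b = percent_positive(shuffled).sort_values(["cluster", "group"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_endothelial_reporter_recovery(self):
        """With endothelial capture 0.6 vs 0.05 elsewhere and 500 cells per
        stratum, endothelial percent-positive exceeds every other cluster and
        its binomial 95% CI excludes the 0.05 level."""
        cfg = ScSimConfig(n_genes=100, n_cells_per_cluster=500, seed=4)
        adata, _ = simulate_sc_matrix(cfg)
        out = percent_positive(adata)
        cat = out[out["group"] == "Cat-LNP"].set_index("cluster")
        endo = [c for c, comp in cfg.clusters.items() if comp == "endothelial"]
        rest = [c for c in cfg.clusters if c not in endo]
        assert cat.loc[endo, "percent"].min() > cat.loc[rest, "percent"].max()
        for c in endo:
            lo, _ = proportion_confint(int(cat.loc[c, "n_positive"]),
                                       int(cat.loc[c, "n_cells"]), method="wilson")
            assert lo > 0.05


class TestDifferentialExpression:
    def test_all_zero_gene_excluded_by_filter(self):
        X = np.ones((10, 3), dtype=int)
        X[:, 1] = 0
        a = tiny_adata(X, ["k"] * 10, ["A"] * 5 + ["B"] * 5)
        de = differential_expression(a, group_a="A", group_b="B")
        assert not de.loc["g1", "tested"] and np.isnan(de.loc["g1", "p"])

    def test_bh_q_monotone_in_p_rank_and_geq_p(self, sc_data):
        adata, _ = sc_data
        de = differential_expression(adata, group_a="Cat-LNP", group_b="PBS")
        tested = de[de["tested"]].sort_values("p")
        assert (tested["q"].cummax() == tested["q"]).all()
        assert (tested["q"] >= tested["p"] - 1e-15).all()

    def test_planted_effect_recovered(self, sc_data):
        adata, truth = sc_data
        de = differential_expression(
            adata, cluster_filter=["EC_capillary", "EC_vascular", "EC_lymphatic"],
            group_a="Cat-LNP", group_b="PBS",
        )
        hits = de.loc[truth["gene"]]
        assert (hits["q"] < 0.05).all() and (hits["log2fc"] > 0).all()

    def test_empty_group_fails_explicitly(self, sc_data):
        adata, _ = sc_data
        with pytest.raises(ValueError, match="empty group"):
            differential_expression(adata, group_a="Cat-LNP", group_b="no-such")

    def test_label_shuffle_yields_uniform_p(self, sc_data):
        """Permuting group labels within one group's cells gives ~uniform p
        (KS at alpha=0.01 over >= 1000 tested genes)."""
        from scipy.stats import kstest

        adata, truth = sc_data
        cells = adata[adata.obs["group"] == "PBS"].copy()
        rng = np.random.default_rng(6)
        cells.obs["group"] = rng.permutation(
            ["x"] * (cells.n_obs // 2) + ["y"] * (cells.n_obs - cells.n_obs // 2)
        )
        de = differential_expression(cells, group_a="x", group_b="y")
        p = de[de["tested"]]["p"]
        assert len(p) >= 1000
        assert kstest(p, "uniform").pvalue > 0.01


class TestTopUpregulated:
    def _de_with_planted(self, n_planted, seed=7):
        cfg = ScSimConfig(
            n_genes=400, n_cells_per_cluster=80, avhh_capture_prob={},
            de_block=tuple((f"gene{i:04d}", "Cat-LNP", 2.0)
                           for i in range(1, n_planted + 1)),
            seed=seed,
        )
        adata, truth = simulate_sc_matrix(cfg)
        de = differential_expression(adata, group_a="Cat-LNP", group_b="PBS")
        return de, list(truth["gene"])

    def test_recovers_planted_positives(self):
        de, planted = self._de_with_planted(12)
        top = top_upregulated(de, 10)
        assert len(top) == 10 and set(top) <= set(planted)

    def test_no_significant_genes_gives_empty_list(self):
        de, _ = self._de_with_planted(12)
        null = de.copy()
        null["p"] = 1.0
        assert top_upregulated(null, 10) == []

    def test_k1_is_smallest_p_upregulated(self):
        de, _ = self._de_with_planted(12)
        top = top_upregulated(de, 1)
        up = de[de["tested"] & (de["p"] < 0.05) & (de["log2fc"] > 0)]
        assert top == [up["p"].idxmin()]


class TestORA:
    def test_matches_exhaustive_enumeration_small_background(self):
        """Upper-tail hypergeometric p equals explicit enumeration over all
        equally likely query draws from a <= 25-gene background."""
        background = [f"b{i}" for i in range(20)]
        gene_sets = {"s1": background[:8], "s2": background[5:11],
                     "s3": ["x1", "x2"]}
        query = ["b0", "b1", "b2", "b6", "b12", "b15"]
        out = ora_hypergeometric(query, gene_sets, background, alpha=0.05)
        n = len(query)
        for name, members in gene_sets.items():
            inset = set(members) & set(background)
            obs = len(inset & set(query))
            hits = total = 0
            for draw in itertools.combinations(background, n):
                hits += len(inset & set(draw)) >= obs
                total += 1
            assert out.loc[name, "p"] == pytest.approx(hits / total, abs=1e-12)

    def test_disjoint_set_p_is_one(self):
        out = ora_hypergeometric(["a"], {"s": ["b", "c"]}, ["a", "b", "c"])
        assert out.loc["s", "p"] == 1.0 and out.loc["s", "overlap"] == 0

    def test_query_equals_background_saturates(self):
        bg = ["a", "b", "c", "d"]
        out = ora_hypergeometric(bg, {"s": ["a", "b"]}, bg)
        assert out.loc["s", "overlap"] == out.loc["s", "set_size"] == 2
        assert out.loc["s", "p"] == 1.0

    def test_perfect_containment_small_p(self):
        bg = [f"b{i}" for i in range(100)]
        query = bg[:10]
        out = ora_hypergeometric(query, {"s": bg[:20]}, bg)
        # all 10 query genes inside a 20-gene set: p = C(20,10)/C(100,10) region
        exact = sum(
            math.comb(20, k) * math.comb(80, 10 - k) for k in range(10, 11)
        ) / math.comb(100, 10)
        assert out.loc["s", "p"] == pytest.approx(exact, rel=1e-9)

    def test_query_outside_background_rejected(self):
        with pytest.raises(ValueError, match="outside background"):
            ora_hypergeometric(["z"], {"s": ["a"]}, ["a", "b"])
        with pytest.raises(ValueError, match="empty background"):
            ora_hypergeometric([], {"s": ["a"]}, [])

    def test_gmt_roundtrip(self, tmp_path):
        gmt = tmp_path / "sets.gmt"
        gmt.write_text("pathwayA\tdesc\tg1\tg2\tg3\npathwayB\tdesc\tg2\tg4\n")
        sets = read_gene_sets(gmt)
        assert sets["pathwayA"] == ["g1", "g2", "g3"]
        assert sets["pathwayB"] == ["g2", "g4"]
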