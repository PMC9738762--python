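"""Count normalization, program scoring, double-hit, and cluster erosion."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import sparse, stats

from secdrug.sc_screen import (
    GeneProgram,
    detect_cluster_erosion,
    double_hit,
    normalize_counts,
    read_cell_matrix,
    read_programs_yaml,
    score_program,
    transfer_labels,
)
from secdrug.synthetic import simulate_sc_counts


def make_adata(counts, clusters, genes=None):
    counts = np.asarray(counts)
    genes = genes or [f"g{i}" for i in range(counts.shape[1])]
    obs = pd.DataFrame(
        {"cluster": clusters},
        index=[f"c{i}" for i in range(counts.shape[0])],
    )
    return ad.AnnData(X=counts.astype(np.int64), obs=obs,
                      var=pd.DataFrame(index=pd.Index(genes)))


class TestNormalizeCounts:
    def test_definition_at_target_depth(self):
        counts = np.zeros((1, 3), dtype=int)
        counts[0] = [100, 9900, 0]
        out = normalize_counts(make_adata(counts, ["a"]))
        assert out.X[0, 0] == pytest.approx(np.log1p(100.0))

    def test_depth_invariance(self):
        counts = np.array([[10, 30, 60], [20, 60, 120]])
        out = normalize_counts(make_adata(counts, ["a", "a"]))
        np.testing.assert_allclose(out.X[0], out.X[1], rtol=1e-12)

    def test_hand_computed_example(self):
        counts = np.array([[1, 2, 3], [4, 0, 6], [0, 0, 2]])
        out = normalize_counts(make_adata(counts, list("aaa")))
        depth = counts.sum(axis=1, keepdims=True)
        expected = np.log1p(counts / depth * 10_000.0)
        np.testing.assert_allclose(out.X, expected, rtol=1e-12)

    def test_zero_depth_cells_dropped_with_warning(self):
        counts = np.array([[1, 2], [0, 0]])
        with pytest.warns(UserWarning, match="zero-depth"):
            out = normalize_counts(make_adata(counts, ["a", "b"]))
        assert out.n_obs == 1

    def test_all_zero_matrix_hard_error(self):
        with pytest.raises(ValueError, match="all-zero"):
            normalize_counts(make_adata(np.zeros((2, 2), dtype=int), ["a", "b"]))

    def test_sparse_matches_dense(self):
        counts = np.array([[5, 0, 3], [1, 2, 0]])
        dense = normalize_counts(make_adata(counts, ["a", "b"]))
        adata = make_adata(counts, ["a", "b"])
        adata.X = sparse.csr_matrix(adata.X)
        sp = normalize_counts(adata)
        np.testing.assert_allclose(sp.X.toarray(), dense.X, rtol=1e-12)


class TestScoreProgram:
    def test_saturated_cluster_fraction_positive_is_one(self):
        counts = np.array([[5, 1], [3, 0], [7, 2]])
        adata = normalize_counts(make_adata(counts, ["a", "a", "a"],
                                            genes=["NAMPT", "other"]))
        res = score_program(adata, GeneProgram("nampt", ["NAMPT"]))
        assert res.loc["a", "fraction_positive"] == 1.0
        assert res.loc["a", "n_cells"] == 3

    def test_planted_nad_salvage_cluster_has_max_score(self):
        pre, _, man = simulate_sc_counts(seed=0)
        adata = normalize_counts(pre)
        res = score_program(adata, GeneProgram("nad", ["NAMPT", "NAPRT", "PSAT1"]))
        assert res["mean_score"].idxmax() == "PSAT1_high"

    def test_planted_emt_cluster_with_down_gene(self):
        pre, _, _ = simulate_sc_counts(seed=1)
        adata = normalize_counts(pre)
        prog = GeneProgram("EMT", ["VIM", "CDH1"], {"VIM": 1, "CDH1": -1})
        res = score_program(adata, prog)
        assert res["mean_score"].idxmax() == "EMT"

    def test_gene_and_cell_order_invariance(self):
        pre, _, _ = simulate_sc_counts(
            n_cells_per_cluster={"base": 30, "PSAT1_high": 30}, seed=2
        )
        adata = normalize_counts(pre)
        prog = GeneProgram("nad", ["NAMPT", "NAPRT", "PSAT1"])
        base = score_program(adata, prog)
        rng = np.random.default_rng(0)
        shuffled = adata[rng.permutation(adata.n_obs),
                         rng.permutation(adata.n_vars)].copy()
        again = score_program(shuffled, GeneProgram("nad", ["PSAT1", "NAMPT", "NAPRT"]))
        pd.testing.assert_frame_equal(
            base.sort_index()[["mean_score", "fraction_positive", "n_cells"]],
            again.sort_index()[["mean_score", "fraction_positive", "n_cells"]],
        )

    def test_fraction_positive_monotone_in_counts(self):
        counts = np.array([[0, 0, 5], [1, 0, 5], [1, 1, 5]])
        adata = normalize_counts(make_adata(counts, list("abc"),
                                            genes=["x", "y", "z"]))
        res = score_program(adata, GeneProgram("p", ["x", "y"]))
        fp = res.loc[list("abc"), "fraction_positive"].to_numpy()
        assert np.all(np.diff(fp) >= 0)

    def test_absent_genes_dropped_with_warning_and_all_absent_error(self):
        counts = np.array([[1, 2], [3, 4]])
        adata = normalize_counts(make_adata(counts, ["a", "b"], genes=["x", "y"]))
        with pytest.warns(UserWarning, match="absent"):
            score_program(adata, GeneProgram("p", ["x", "ghost"]))
        with pytest.raises(ValueError, match="no gene"):
            score_program(adata, GeneProgram("p", ["ghost"]))

    def test_duplicate_program_genes_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            GeneProgram("p", ["x", "x"])


class TestDoubleHit:
    def ranking_table(self):
        return pd.DataFrame(
            {"drug_id": ["A", "B"], "rank": [1, 2],
             "kill_count": [5, 3]}
        )

    def screen(self, fraction):
        return pd.DataFrame(
            {"fraction_positive": [fraction], "mean_score": [1.0],
             "n_cells": [100]},
            index=pd.Index(["res"], name="cluster"),
        )

    def test_rank1_full_coverage_scores_one(self):
        out = double_hit(self.ranking_table(), {"A": self.screen(1.0)}, {"res"})
        assert out.loc[0, "double_hit"] == pytest.approx(1.0)

    def test_rank1_zero_coverage_scores_zero(self):
        out = double_hit(self.ranking_table(), {"A": self.screen(0.0)}, {"res"})
        assert out.loc[0, "double_hit"] == 0.0

    def test_cell_weighted_coverage(self):
        screen = pd.DataFrame(
            {"fraction_positive": [1.0, 0.0], "mean_score": [1, 0],
             "n_cells": [300, 100]},
            index=pd.Index(["r1", "r2"], name="cluster"),
        )
        out = double_hit(self.ranking_table(), {"A": screen}, {"r1", "r2"})
        assert out.loc[0, "target_coverage"] == pytest.approx(0.75)

    def test_empty_flagged_set_warns_and_uses_all(self):
        with pytest.warns(UserWarning, match="all clusters"):
            out = double_hit(self.ranking_table(), {"A": self.screen(0.5)}, set())
        assert out.loc[0, "target_coverage"] == pytest.approx(0.5)

    def test_planted_drug_tops_table(self):
        """Rank-1 planted drug whose target program is high in flagged
        clusters dominates the double-hit ordering."""
        from secdrug.core import classify_resistance, rank_secdrugs
        from secdrug.synthetic import example_drug_annotations, simulate_pgx_panel

        panel, man = simulate_pgx_panel(n_lines=60, n_drugs=12, seed=21)
        cls = classify_resistance(panel, "docetaxel", 0.75)
        ranking = rank_secdrugs(panel, cls,
                                drug_annotations=example_drug_annotations())
        pre, _, _ = simulate_sc_counts(seed=21)
        adata = normalize_counts(pre)
        nad = score_program(adata, GeneProgram("nad", ["NAMPT", "NAPRT", "PSAT1"]))
        # competitors get a program over filler genes (low positivity)
        filler = score_program(adata, GeneProgram("null", ["G0001", "G0002", "G0003"]))
        screens = {d: filler for d in ranking.table["drug_id"]}
        screens["FK866"] = nad
        out = double_hit(ranking, screens, {"PSAT1_high", "EMT", "stem"})
        assert out.loc[0, "drug_id"] == man.truth["planted_secdrugs"][0]


class TestClusterErosion:
    def test_identical_compositions_not_eroded(self):
        labels = ["a"] * 80 + ["b"] * 20
        out = detect_cluster_erosion(labels, labels)
        assert not out["eroded"].any()

    def test_planted_total_erosion_flagged(self):
        pre = ["a"] * 400 + ["b"] * 100
        post = ["a"] * 500
        out = detect_cluster_erosion(pre, post)
        assert bool(out.loc["b", "eroded"])
        assert out.loc["b", "prop_post"] == 0.0

    def test_fisher_p_matches_hypergeometric_sum(self):
        """The per-cluster p equals the two-sided hypergeometric tail."""
        pre = ["a"] * 90 + ["b"] * 10
        post = ["a"] * 97 + ["b"] * 3
        out = detect_cluster_erosion(pre, post)
        table = [[10, 90], [3, 97]]
        expected = stats.fisher_exact(table)[1]
        assert out.loc["b", "p"] == pytest.approx(expected, rel=1e-12)
        # independent check via hypergeometric enumeration
        n_draw, k_total, n_total = 100, 13, 200
        probs = stats.hypergeom.pmf(np.arange(0, k_total + 1), n_total,
                                    k_total, n_draw)
        p_enum = probs[probs <= probs[10] * (1 + 1e-9)].sum()
        assert out.loc["b", "p"] == pytest.approx(p_enum, rel=1e-9)

    def test_planted_psat1_high_erosion_only(self):
        pre, post, man = simulate_sc_counts(seed=5)
        out = detect_cluster_erosion(
            normalize_counts(pre), normalize_counts(post)
        )
        assert set(out.index[out["eroded"]]) == set(man.truth["eroded_clusters"])

    def test_half_rule_blocks_modest_drops(self):
        # significant but less-than-half drop must not be called erosion
        pre = ["a"] * 600 + ["b"] * 400
        post = ["a"] * 700 + ["b"] * 300
        out = detect_cluster_erosion(pre, post)
        assert out.loc["b", "p"] < 0.05
        assert not bool(out.loc["b", "eroded"])


class TestIOAndTransfer:
    def test_mtx_round_trip(self, tmp_path):
        from scipy.io import mmwrite

        counts = np.array([[0, 2, 1], [3, 0, 0]])  # cells x genes
        mmwrite(str(tmp_path / "m.mtx"), sparse.csr_matrix(counts.T))
        (tmp_path / "barcodes.tsv").write_text("bc1\nbc2\n")
        (tmp_path / "features.tsv").write_text("gA\ngB\ngC\n")
        (tmp_path / "meta.csv").write_text(
            "barcode,cluster,condition\nbc1,x,pre\nbc2,y,pre\n")
        adata = read_cell_matrix(tmp_path / "m.mtx", tmp_path / "barcodes.tsv",
                                 tmp_path / "features.tsv", tmp_path / "meta.csv")
        np.testing.assert_array_equal(adata.X.toarray(), counts)
        assert list(adata.obs["cluster"]) == ["x", "y"]

    def test_programs_yaml(self, tmp_path):
        (tmp_path / "p.yaml").write_text(
            "- name: EMT\n  genes: [VIM, CDH1]\n  down: [CDH1]\n"
        )
        progs = read_programs_yaml(tmp_path / "p.yaml")
        assert progs[0].directions == {"VIM": 1, "CDH1": -1}

    def test_nearest_centroid_transfer_recovers_labels(self):
        pre, post, _ = simulate_sc_counts(
            n_cells_per_cluster={"base": 80, "EMT": 80},
            erosion_spec=None, seed=9,
        )
        pre_n = normalize_counts(pre)
        post_n = normalize_counts(post)
        truth = post_n.obs["cluster"].copy()
        post_n.obs = post_n.obs.drop(columns="cluster")
        out = transfer_labels(pre_n, post_n)
        agree = (out.obs["cluster"].to_numpy() == truth.to_numpy()).mean()
        assert agree >= 0.95
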