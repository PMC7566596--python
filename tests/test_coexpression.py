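import math

import anndata as ad
import networkx as nx
import numpy as np
import pytest

from carnet.annotations import GeneModel, GenomicInterval, SuperEnhancer
from carnet.coexpression import (
    QCParams,
    coexpression_contingency,
    genes_in_interacting_ses,
    partner_gene_screen,
    positivity,
    qc_filter_cells,
)
from carnet.simulate import SimConfig, simulate_cell_counts


def adata_from(x, genes, condition="c"):
    a = ad.AnnData(X=np.asarray(x, dtype=np.int64))
    a.var_names = genes
    a.obs_names = [f"cell{i}" for i in range(a.n_obs)]
    a.obs["condition"] = condition
    return a


class TestQC:
    def test_low_gene_count_cell_removed(self):
        rng = np.random.default_rng(0)
        x = rng.integers(1, 5, size=(5, 400))
        x[0, 10:] = 0  # cell 0 detects only 10 genes
        a = adata_from(x, [f"g{i}" for i in range(400)])
        out = qc_filter_cells(a, QCParams(min_genes=300, gene_count_upper_percentile=100))
        assert "cell0" not in out.obs_names and out.n_obs == 4

    def test_permissive_params_keep_all_cells(self):
        x = np.ones((4, 10), dtype=int)
        a = adata_from(x, [f"g{i}" for i in range(10)])
        out = qc_filter_cells(
            a, QCParams(min_genes=0, gene_count_upper_percentile=100, mito_upper=1.0)
        )
        assert out.n_obs == 4

    def test_percentile_rule_removes_top_one_percent(self):
        """1,000 cells, 20 planted high-gene-count outliers, 99th pct cap.

        The per-sample percentile rule removes exactly the cells above the
        99th percentile of the detected-gene distribution (the top 10),
        not all 20 planted outliers.
        """
        rng = np.random.default_rng(1)
        n_genes = 600
        x = np.zeros((1000, n_genes), dtype=int)
        base = rng.integers(350, 400, size=1000)
        for i in range(1000):
            x[i, : base[i]] = 1
        outliers = rng.choice(1000, 20, replace=False)
        for rank, i in enumerate(sorted(outliers)):
            x[i, :] = 0
            x[i, : 500 + rank] = 1  # distinct counts 500..519
        a = adata_from(x, [f"g{i}" for i in range(n_genes)])
        out = qc_filter_cells(a, QCParams(min_genes=0, mito_upper=1.0,
                                          gene_count_upper_percentile=99))
        assert a.n_obs - out.n_obs == 10

    def test_mito_fraction_cap(self):
        x = np.ones((3, 10), dtype=int)
        x[0, 9] = 100  # cell 0 dominated by the mito gene; others at 1/10
        a = adata_from(x, [f"g{i}" for i in range(9)] + ["MT-X"])
        out = qc_filter_cells(
            a, QCParams(min_genes=0, gene_count_upper_percentile=100, mito_upper=0.20)
        )
        assert out.n_obs == 2 and "cell0" not in out.obs_names

    def test_all_cells_removed_errors(self):
        x = np.ones((3, 4), dtype=int)
        a = adata_from(x, [f"g{i}" for i in range(4)])
        with pytest.raises(ValueError, match="every cell"):
            qc_filter_cells(a, QCParams(min_genes=300))


class TestPositivity:
    def test_zero_gene_all_negative_and_count_one_positive(self):
        a = adata_from([[0, 1], [0, 3]], ["dead", "alive"])
        assert not positivity(a, "dead").any()
        assert positivity(a, "alive").all()

    def test_absent_gene_errors(self):
        a = adata_from([[1]], ["g"])
        with pytest.raises(KeyError):
            positivity(a, "nope")


class TestContingency:
    def test_hand_table(self):
        # treated: 50 anchor+, 40 with partner; control: 14 anchor+, 4 with partner
        tr = np.zeros((60, 2), dtype=int)
        tr[:50, 0] = 1
        tr[:40, 1] = 1
        ct = np.zeros((20, 2), dtype=int)
        ct[:14, 0] = 1
        ct[:4, 1] = 1
        cont, res = coexpression_contingency(
            adata_from(tr, ["A", "P"]), adata_from(ct, ["A", "P"]), "A", "P"
        )
        assert (cont.a, cont.b, cont.c, cont.d) == (40, 10, 4, 10)
        assert res.odds_ratio == pytest.approx(10)

    def test_identical_matrices_give_or_one(self):
        x = np.zeros((30, 2), dtype=int)
        x[:20, 0] = 1
        x[:8, 1] = 2
        a, b = adata_from(x, ["A", "P"]), adata_from(x, ["A", "P"])
        _, res = coexpression_contingency(a, b, "A", "P")
        assert res.odds_ratio == pytest.approx(1.0)

    def test_missing_anchor_positive_condition_errors(self):
        tr = adata_from([[1, 1]], ["A", "P"])
        ct = adata_from([[0, 1]], ["A", "P"])
        with pytest.raises(ValueError, match="control"):
            coexpression_contingency(tr, ct, "A", "P")

    def test_margins_match_independent_positivity(self):
        cfg = SimConfig(seed=21)
        cfg.coexpr.n_cells_treated = cfg.coexpr.n_cells_control = 2000
        tr, ct = simulate_cell_counts(cfg)
        cont, _ = coexpression_contingency(tr, ct, "ANCHOR", "PARTNER")
        assert cont.a + cont.b == int(positivity(tr, "ANCHOR").sum())
        assert cont.c + cont.d == int(positivity(ct, "ANCHOR").sum())

    @pytest.mark.parametrize("omega", [2.0, 5.0, 40.0])
    def test_parameter_recovery_within_three_se(self, omega):
        cfg = SimConfig(seed=int(omega) + 100)
        cfg.coexpr.n_cells_treated = cfg.coexpr.n_cells_control = 20_000
        cfg.coexpr.partner_or = {"P": omega}
        tr, ct = simulate_cell_counts(cfg)  # ~10,000 anchor-positive per condition
        cont, res = coexpression_contingency(tr, ct, "ANCHOR", "P")
        se = math.sqrt(1 / cont.a + 1 / cont.b + 1 / cont.c + 1 / cont.d)
        assert abs(math.log(res.odds_ratio) - math.log(omega)) < 3 * se


class TestScreen:
    def test_single_candidate_ranks_first(self):
        x = np.zeros((30, 2), dtype=int)
        x[:20, 0] = 1
        x[:10, 1] = 1
        a, b = adata_from(x, ["A", "P"]), adata_from(x, ["A", "P"])
        df, skipped = partner_gene_screen(a, b, "A", ["P"])
        assert list(df["rank"]) == [1] and skipped == []

    def test_absent_candidates_reported_skipped(self):
        x = np.zeros((5, 2), dtype=int)
        x[:, 0] = 1
        x[:2, 1] = 1
        a = adata_from(x, ["A", "P"])
        df, skipped = partner_gene_screen(a, a, "A", ["P", "MISSING"])
        assert skipped == ["MISSING"] and len(df) == 1

    def test_planted_or_ordering_recovered(self):
        cfg = SimConfig(seed=31)
        cfg.coexpr.n_cells_treated = cfg.coexpr.n_cells_control = 10_000
        cfg.coexpr.partner_or = {"G_HI": 8.0, "G_MID": 2.0, "G_NULL": 1.0}
        tr, ct = simulate_cell_counts(cfg)
        df, _ = partner_gene_screen(tr, ct, "ANCHOR", ["G_NULL", "G_MID", "G_HI"])
        assert list(df["gene"]) == ["G_HI", "G_MID", "G_NULL"]

    def test_screen_or_matches_standalone_contingency(self):
        cfg = SimConfig(seed=41)
        cfg.coexpr.n_cells_treated = cfg.coexpr.n_cells_control = 3000
        tr, ct = simulate_cell_counts(cfg)
        df, _ = partner_gene_screen(tr, ct, "ANCHOR", ["PARTNER"])
        _, res = coexpression_contingency(tr, ct, "ANCHOR", "PARTNER")
        assert df.loc[0, "odds_ratio"] == pytest.approx(res.odds_ratio)


class TestGenesInInteractingSEs:
    def setup_method(self):
        self.ses = [
            SuperEnhancer("ANCHOR_SE", GenomicInterval("chr1", 100, 200)),
            SuperEnhancer("SE_X", GenomicInterval("chr2", 100, 300)),
            SuperEnhancer("SE_Y", GenomicInterval("chr3", 100, 300)),
        ]
        self.genes = [
            GeneModel("G_anchor", GenomicInterval("chr1", 50, 400)),
            GeneModel("G_x", GenomicInterval("chr2", 150, 250)),
            GeneModel("G_y", GenomicInterval("chr3", 150, 250)),
            GeneModel("G_far", GenomicInterval("chr4", 0, 100)),
        ]

    def test_no_edges_gives_empty_list(self):
        g = nx.Graph()
        g.add_node("ANCHOR_SE")
        assert genes_in_interacting_ses(g, "ANCHOR_SE", self.genes, self.ses) == []

    def test_two_adjacent_ses_two_genes(self):
        g = nx.Graph([("ANCHOR_SE", "SE_X"), ("ANCHOR_SE", "SE_Y")])
        out = genes_in_interacting_ses(g, "ANCHOR_SE", self.genes, self.ses)
        assert sorted(out) == ["G_x", "G_y"]

    def test_gene_spanning_two_adjacent_ses_listed_once(self):
        ses = self.ses + [SuperEnhancer("SE_X2", GenomicInterval("chr2", 200, 400))]
        g = nx.Graph([("ANCHOR_SE", "SE_X"), ("ANCHOR_SE", "SE_X2")])
        out = genes_in_interacting_ses(g, "ANCHOR_SE", self.genes, ses)
        assert out.count("G_x") == 1

    def test_anchor_own_genes_excluded(self):
        g = nx.Graph([("ANCHOR_SE", "SE_X")])
        out = genes_in_interacting_ses(g, "ANCHOR_SE", self.genes, self.ses)
        assert "G_anchor" not in out

    def test_absent_anchor_errors(self):
        with pytest.raises(KeyError):
            genes_in_interacting_ses(nx.Graph(), "ANCHOR_SE", self.genes, self.ses)
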