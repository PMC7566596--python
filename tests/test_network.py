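import itertools

import networkx as nx
import numpy as np
import pytest
from scipy.stats import zipf

from carnet.annotations import GenomicInterval, SuperEnhancer
from carnet.network import (
    SEContactTable,
    call_interactions,
    count_se_pair_contacts,
    fit_power_law,
    hub_continuity,
    identify_hubs,
    interaction_threshold,
    network_edge_table,
    se_end_totals,
    split_edges_by_chromosome,
)
from carnet.simulate import simulate_read_pairs

from conftest import make_pairs


def brute_force_contacts(pairs, ses):
    """Independent oracle: triple loop over (pair, SE_i, SE_j)."""
    counts = {}
    for row in pairs.itertuples(index=False):
        rna = GenomicInterval(row.rna_chrom, row.rna_start, row.rna_end)
        dna = GenomicInterval(row.dna_chrom, row.dna_start, row.dna_end)
        for si, sj in itertools.product(ses, ses):
            if si.se_id == sj.se_id:
                continue
            if rna.overlaps(si.interval) and dna.overlaps(sj.interval):
                key = tuple(sorted((si.se_id, sj.se_id)))
                counts[key] = counts.get(key, 0) + 1
    # unordered double-count: each ordered qualifying (i,j) was added once
    return counts


class TestCounting:
    def test_single_pair_single_contact(self, toy_ses):
        pairs = make_pairs([("chr1", 150, 160, "chr1", 650, 660)])
        t = count_se_pair_contacts(pairs, toy_ses)
        assert t.counts == {("SE_A", "SE_B"): 1}

    def test_direction_collapses_to_unordered_key(self, toy_ses):
        pairs = make_pairs(
            [("chr1", 150, 160, "chr1", 650, 660), ("chr1", 650, 660, "chr1", 150, 160)]
        )
        t = count_se_pair_contacts(pairs, toy_ses)
        assert t.counts == {("SE_A", "SE_B"): 2}

    def test_self_pair_excluded(self, toy_ses):
        pairs = make_pairs([("chr1", 110, 120, "chr1", 150, 160)])
        t = count_se_pair_contacts(pairs, toy_ses)
        assert t.counts == {}

    def test_matches_brute_force_oracle(self, sim_config, annotations):
        pairs = simulate_read_pairs(
            sim_config, annotations, n_pairs=10_000,
            hub_spec={"SE001": 20.0}, p_inter=0.6,
        )
        fast = count_se_pair_contacts(pairs, annotations.ses).counts
        slow = brute_force_contacts(pairs, annotations.ses)
        assert fast == slow

    def test_normalization_uses_sample_total(self, toy_ses):
        pairs = make_pairs([("chr1", 150, 160, "chr1", 650, 660)])
        t = count_se_pair_contacts(pairs, toy_ses, total_pairs=100)
        assert t.norm_counts() == {("SE_A", "SE_B"): 0.01}

    def test_directional_end_totals(self, toy_ses):
        pairs = make_pairs(
            [("chr1", 150, 160, "chr1", 650, 660), ("chr1", 150, 160, "chr2", 0, 50)]
        )
        df = se_end_totals(pairs, toy_ses).set_index("se_id")
        assert df.loc["SE_A", "rna_end_count"] == 2
        assert df.loc["SE_B", "dna_end_count"] == 1


class TestThresholdAndCalling:
    def test_hand_percentile_with_interpolation(self):
        counts = {(f"A{i}", f"B{i}"): i for i in range(1, 21)}
        t = SEContactTable("s", counts, total_pairs=10**8)
        # norm counts 1..20 (x 1e-8); 95th percentile = 19.05e-8
        assert interaction_threshold(t, 95) == pytest.approx(19.05e-8)

    def test_all_equal_values_give_that_value(self):
        t = SEContactTable("s", {("A", "B"): 5, ("A", "C"): 5}, 100)
        assert interaction_threshold(t, 95) == pytest.approx(0.05)

    def test_percentile_zero_is_min(self):
        t = SEContactTable("s", {("A", "B"): 1, ("A", "C"): 9}, 100)
        assert interaction_threshold(t, 0) == pytest.approx(0.01)

    def test_empty_table_errors(self):
        with pytest.raises(ValueError):
            interaction_threshold(SEContactTable("s", {}, 100))

    def test_edges_strictly_above_threshold_and_monotone(self):
        counts = {(f"A{i}", f"B{i}"): i for i in range(1, 11)}
        t = SEContactTable("s", counts, total_pairs=100)
        edge_counts = [
            call_interactions(t, thr).number_of_edges()
            for thr in (0.0, 0.03, 0.05, 0.2)
        ]
        assert edge_counts[0] == 10  # all nonzero pairs
        assert edge_counts == sorted(edge_counts, reverse=True)
        assert edge_counts[-1] == 0  # threshold >= max
        # strictness at a tied value: norm == 0.05 excluded
        assert call_interactions(t, 0.05).number_of_edges() == 5

    def test_isolated_nodes_retained(self, toy_ses):
        t = SEContactTable("s", {("SE_A", "SE_B"): 10}, 100)
        g = call_interactions(t, 0.0, ses=toy_ses)
        assert set(g.nodes) == {"SE_A", "SE_B", "SE_C"}

    def test_scaling_counts_and_total_leaves_network_unchanged(self):
        counts = {(f"A{i}", f"B{i}"): i for i in range(1, 11)}
        t1 = SEContactTable("s", counts, total_pairs=1000)
        t2 = SEContactTable("s", {k: 7 * v for k, v in counts.items()}, 7000)
        thr = interaction_threshold(t1, 80)
        assert interaction_threshold(t2, 80) == pytest.approx(thr)
        e1 = set(map(frozenset, call_interactions(t1, thr).edges))
        e2 = set(map(frozenset, call_interactions(t2, thr).edges))
        assert e1 == e2


class TestEdgeSplit:
    def test_all_same_chromosome_is_intra(self, toy_ses):
        t = SEContactTable("s", {("SE_A", "SE_B"): 10}, 100)
        g = call_interactions(t, 0.0, ses=toy_ses)
        inter, intra = split_edges_by_chromosome(g)
        assert inter == [] and len(intra) == 1

    def test_counts_sum_to_total_edges(self, sim_config, annotations):
        pairs = simulate_read_pairs(sim_config, annotations, n_pairs=50_000, p_inter=0.9)
        t = count_se_pair_contacts(pairs, annotations.ses)
        g = call_interactions(t, 0.0, ses=annotations.ses)
        inter, intra = split_edges_by_chromosome(g)
        assert len(inter) + len(intra) == g.number_of_edges()
        # with p_inter = 0.9 interchromosomal edges dominate
        assert len(inter) > len(intra)


class TestHubs:
    def test_high_degree_minority_are_the_hubs(self):
        # 10 centers each linked to 9 distinct leaves of degree 1:
        # degrees = [9]*10 + [1]*90, 95th percentile = 9 -> centers only
        g = nx.Graph()
        for c in range(10):
            for leaf in range(9):
                g.add_edge(f"hub{c}", f"leaf{c}_{leaf}")
        hs = identify_hubs(g, percentile=95)
        assert hs.ids == {f"hub{c}" for c in range(10)}
        assert hs.resolved_min_degree == pytest.approx(9)

    def test_constant_degree_ties_make_all_hubs(self):
        g = nx.cycle_graph(10)
        hs = identify_hubs(g, percentile=95)
        assert len(hs) == 10

    def test_override_above_max_degree_gives_empty(self):
        g = nx.star_graph(10)
        assert len(identify_hubs(g, min_degree_override=60)) == 0

    def test_edgeless_network_gives_empty_hubset(self):
        g = nx.empty_graph(5)
        assert len(identify_hubs(g)) == 0

    def test_continuity_nested_sets(self):
        a = identify_hubs(nx.Graph([("A", i) for i in range(60)]), min_degree_override=50)
        ab = identify_hubs(
            nx.Graph([("A", i) for i in range(60)] + [("B", i) for i in range(70)]),
            min_degree_override=50,
        )
        ok, violations = hub_continuity([a, ab])
        assert ok and violations == []

    def test_continuity_violation_reported(self):
        a = identify_hubs(nx.Graph([("A", 1), ("A", 2), ("B", 3), ("B", 4)]),
                          min_degree_override=2)
        b = identify_hubs(nx.Graph([("B", 3), ("B", 4), ("B", 5)]),
                          min_degree_override=2)
        ok, violations = hub_continuity([a, b])
        assert not ok and violations == [(0, {"A"})]

    def test_single_time_point_vacuously_continuous(self):
        a = identify_hubs(nx.star_graph(5))
        assert hub_continuity([a])[0]

    def test_designated_hubs_recovered_from_simulation(self, sim_config, annotations):
        planted = {"SE001": 30.0, "SE010": 30.0, "SE030": 25.0}
        pairs = simulate_read_pairs(
            sim_config, annotations, n_pairs=1_000_000, p_inter=0.6, hub_spec=planted
        )
        table = count_se_pair_contacts(pairs, annotations.ses)
        day0 = simulate_read_pairs(
            sim_config, annotations, n_pairs=300_000, p_inter=0.344, seed=77
        )
        thr = interaction_threshold(count_se_pair_contacts(day0, annotations.ses))
        g = call_interactions(table, thr, ses=annotations.ses)
        hubs = identify_hubs(g, percentile=95)
        recall = len(set(planted) & hubs.ids) / len(planted)
        assert recall >= 0.9


class TestPowerLaw:
    def test_exponent_recovery_from_zipf_sample(self):
        degrees = zipf(2.5).rvs(5000, random_state=7)
        fit = fit_power_law(degrees)
        assert abs(fit.alpha - 2.5) <= 0.2
        assert fit.plausible
        # CCDF slope diagnostic ~ -(alpha - 1)
        assert fit.ccdf_slope < -0.8

    def test_constant_degrees_flagged_non_power_law(self):
        fit = fit_power_law([4] * 50)
        assert not fit.plausible

    def test_estimate_invariant_under_node_relabeling(self):
        rng = np.random.default_rng(5)
        degrees = zipf(2.2).rvs(2000, random_state=3)
        g = nx.expected_degree_graph(degrees, seed=1)
        relabeled = nx.relabel_nodes(g, {n: f"x{n}" for n in g.nodes})
        assert fit_power_law(g).alpha == pytest.approx(fit_power_law(relabeled).alpha)

    def test_too_few_nodes_error(self):
        with pytest.raises(ValueError):
            fit_power_law([3, 2, 1])


def test_edge_table_columns():
    t = SEContactTable("s", {("A", "B"): 3}, 100)
    g = call_interactions(t, 0.0)
    df = network_edge_table(g)
    assert list(df.columns) == ["se_i", "se_j", "raw", "norm", "inter"]
    assert df.loc[0, "raw"] == 3
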