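"""Delta pairs, interaction-network inference, trends, main component."""

import numpy as np
import pandas as pd
import pytest

import bariomics as bm

from conftest import make_table


def meta_frame(rows):
    """rows: (sample_id, subject, timepoint, bmi)."""
    return bm.validate_metadata(pd.DataFrame(
        [{"subject_id": s, "timepoint": tp, "bmi": bmi} for _, s, tp, bmi in rows],
        index=pd.Index([r[0] for r in rows], name="sample_id")))


class TestBuildDeltaPairs:
    def _table(self, sample_ids, values):
        return make_table(np.asarray(values, float), sample_ids=sample_ids,
                          stage="logged")

    def test_three_timepoints_give_two_pairs(self):
        table = self._table(["s1", "s2", "s3"], [[0.0, 0], [1, 1], [2, 2]])
        meta = meta_frame([("s1", "P", "A", 40), ("s2", "P", "B", 39),
                          ("s3", "P", "C", 36)])
        pairs = bm.build_delta_pairs(table, meta)
        assert [(p.t_from, p.t_to) for p in pairs] == [("A", "B"), ("B", "C")]

    def test_missing_intermediate_gives_adjacent_sampled_pair(self):
        table = self._table(["s1", "s2"], [[0.0, 0], [1, 1]])
        meta = meta_frame([("s1", "P", "A", 40), ("s2", "P", "C", 36)])
        pairs = bm.build_delta_pairs(table, meta)
        assert [(p.t_from, p.t_to) for p in pairs] == [("A", "C")]

    def test_delta_arithmetic(self):
        table = self._table(["s1", "s2"], [[0.5, 1.0], [0.7, 0.4]])
        meta = meta_frame([("s1", "P", "A", 40), ("s2", "P", "B", 39)])
        pairs = bm.build_delta_pairs(table, meta)
        np.testing.assert_allclose(pairs[0].delta, [0.2, -0.6])
        np.testing.assert_allclose(pairs[0].x_from, [0.5, 1.0])

    def test_lean_and_single_visit_subjects_contribute_nothing(self):
        table = self._table(["s1", "s2"], [[0.0, 0], [1, 1]])
        meta = meta_frame([("s1", "P1", "A", 40), ("s2", "L1", "H", 22)])
        assert bm.build_delta_pairs(table, meta) == []

    def test_duplicate_subject_timepoint_rejected(self):
        table = self._table(["s1", "s2"], [[0.0, 0], [1, 1]])
        meta = meta_frame([("s1", "P", "A", 40), ("s2", "P2", "A", 41)])
        meta.loc["s2", "subject_id"] = "P"  # bypass metadata-level check
        with pytest.raises(ValueError, match="twice"):
            bm.build_delta_pairs(table, meta)

    def test_requires_logged_stage(self, toy):
        with pytest.raises(ValueError, match="log"):
            bm.build_delta_pairs(toy[0], toy[1])


class TestInferNetwork:
    def test_noiseless_dynamics_inverted_exactly(self):
        B = bm.random_interaction_matrix(8, density=0.12, strength=0.3,
                                         self_decay=0.3, seed=2)
        pairs, taxa = bm.simulate_delta_pairs(B, n_pairs=150, noise_sd=0.0, seed=3)
        net = bm.infer_network(pairs, taxa, alpha=0.05)
        truth = {(taxa[j], taxa[i]) for i in range(8) for j in range(8)
                 if B[i, j] != 0}
        got = {(r.source, r.target) for r in net.edges.itertuples()}
        assert got == truth
        for r in net.edges.itertuples():
            i, j = taxa.index(r.target), taxa.index(r.source)
            assert abs(r.beta - B[i, j]) < 1e-6
            assert r.sign == np.sign(B[i, j])

    def test_underdetermined_design_rejected(self):
        B = np.zeros((10, 10))
        pairs, taxa = bm.simulate_delta_pairs(B, n_pairs=8, noise_sd=0.1, seed=0)
        with pytest.raises(ValueError, match="coarser rank"):
            bm.infer_network(pairs, taxa)

    def test_rank_deficient_design_reports_condition_number(self):
        B = np.zeros((3, 3))
        pairs, taxa = bm.simulate_delta_pairs(B, n_pairs=30, noise_sd=0.1, seed=1)
        for p in pairs:  # make two coordinates identical
            p.x_from[1] = p.x_from[0]
        with pytest.raises(ValueError, match="condition"):
            bm.infer_network(pairs, taxa)

    def test_retained_edges_meet_bonferroni_threshold(self):
        B = bm.random_interaction_matrix(6, density=0.2, strength=0.3,
                                         self_decay=0.4, seed=0)
        pairs, taxa = bm.simulate_delta_pairs(B, n_pairs=120, noise_sd=0.1, seed=5)
        net = bm.infer_network(pairs, taxa, alpha=0.05)
        assert net.n_tests == 36
        assert (net.edges["p_raw"] <= 0.05 / 36).all()

    def test_edge_set_invariant_under_taxon_permutation(self):
        B = bm.random_interaction_matrix(6, density=0.2, strength=0.4,
                                         self_decay=0.3, seed=6)
        pairs, taxa = bm.simulate_delta_pairs(B, n_pairs=120, noise_sd=0.05, seed=7)
        net1 = bm.infer_network(pairs, taxa, alpha=0.05)
        perm = np.random.default_rng(0).permutation(len(taxa))
        pairs2 = [bm.DeltaPair(p.subject_id, p.t_from, p.t_to,
                               p.x_from[perm], p.delta[perm]) for p in pairs]
        taxa2 = [taxa[i] for i in perm]
        net2 = bm.infer_network(pairs2, taxa2, alpha=0.05)
        edges1 = {(r.source, r.target, r.sign) for r in net1.edges.itertuples()}
        edges2 = {(r.source, r.target, r.sign) for r in net2.edges.itertuples()}
        assert edges1 == edges2

    def test_no_self_flag_removes_diagonal_terms(self):
        B = bm.random_interaction_matrix(5, density=0.2, strength=0.4,
                                         self_decay=0.4, seed=8)
        pairs, taxa = bm.simulate_delta_pairs(B, n_pairs=100, noise_sd=0.05, seed=9)
        net = bm.infer_network(pairs, taxa, alpha=0.05, include_self=False)
        assert net.n_tests == 20
        assert (net.edges["source"] != net.edges["target"]).all()


class TestMainComponent:
    def _net(self, edge_list):
        edges = pd.DataFrame(
            [{"source": a, "target": b, "beta": 1.0, "p_raw": 1e-9, "sign": 1}
             for a, b in edge_list])
        nodes = sorted({n for e in edge_list for n in e})
        return bm.InteractionNetwork(nodes=nodes, edges=edges, alpha=0.05,
                                     n_tests=100)

    def test_largest_weak_component_kept(self):
        net = self._net([("a", "b"), ("c", "d"), ("d", "c"), ("d", "e")])
        main = bm.main_component(net)
        assert main.nodes == ["c", "d", "e"]
        assert main.n_edges == 3

    def test_fully_connected_is_identity(self):
        net = self._net([("a", "b"), ("b", "c"), ("c", "a")])
        main = bm.main_component(net)
        assert main.nodes == ["a", "b", "c"]

    def test_empty_network_stays_empty(self):
        empty = bm.InteractionNetwork(
            nodes=["a", "b"], edges=pd.DataFrame(
                columns=["source", "target", "beta", "p_raw", "sign"]),
            alpha=0.05, n_tests=4)
        main = bm.main_component(empty)
        assert main.nodes == []
        assert main.n_edges == 0

    def test_size_tie_broken_lexicographically(self):
        net = self._net([("x", "y"), ("a", "b")])
        main = bm.main_component(net)
        assert main.nodes == ["a", "b"]


class TestRankTrends:
    def test_strictly_increasing_taxon_flagged_positive(self):
        values = np.array([[0.0], [0.5], [1.0], [1.5], [2.0], [2.5]])
        table = make_table(values, stage="logged")
        meta = meta_frame([("S0", "P1", "A", 40), ("S1", "P1", "B", 40),
                          ("S2", "P2", "A", 41), ("S3", "P2", "C", 39),
                          ("S4", "P3", "D", 37), ("S5", "P3", "E", 35)])
        trends = bm.rank_trends(table, meta, rank="phylum")
        assert (trends["trend"] == 1.0).all()

    def test_single_timepoint_trend_missing(self):
        table = make_table(np.ones((2, 1)), stage="logged")
        meta = meta_frame([("S0", "P1", "A", 40), ("S1", "P2", "A", 41)])
        trends = bm.rank_trends(table, meta, rank="phylum")
        assert trends["trend"].isna().all()

    def test_generator_injected_trends_recovered(self):
        """Increasing proteobacteria/fusobacteria, decreasing firmicutes."""
        spec = bm.CohortSpec(seed=21, n_obese=50, n_lean=10,
                             trend_magnitude=0.08)
        table, meta, truth = bm.generate_cohort(spec)
        logged = bm.log_transform(
            bm.collapse_to_rank(table, "genus"), 0.1, 10)
        trends = bm.rank_trends(logged, meta, rank="phylum")
        up = [t for t in trends.index if "Proteobacteria" in t or "Fusobacteria" in t]
        down = [t for t in trends.index if "Firmicutes" in t]
        assert (trends.loc[up, "trend"] == 1.0).all()
        assert (trends.loc[down, "trend"] == -1.0).all()


class TestInteractionModel:
    def test_from_table_through_fit(self, small_cohort):
        table, meta, truth = small_cohort
        logged = bm.log_transform(bm.collapse_to_rank(table, "genus"), 0.1, 10)
        model = bm.InteractionModel.from_table(logged, meta, rank="class")
        net = model.fit(alpha=0.05)
        assert set(net.edges.columns) == {"source", "target", "beta", "p_raw", "sign"}
        assert net.summary().startswith("Interaction network")

    def test_edge_list_round_trip(self, tmp_path):
        B = bm.random_interaction_matrix(5, density=0.2, strength=0.3,
                                         self_decay=0.4, seed=0)
        pairs, taxa = bm.simulate_delta_pairs(B, n_pairs=80, noise_sd=0.05, seed=11)
        net = bm.infer_network(pairs, taxa)
        net.write_edge_list(tmp_path / "edges.tsv")
        back = pd.read_csv(tmp_path / "edges.tsv", sep="\t")
        assert len(back) == net.n_edges
        g = net.to_graph()
        assert g.number_of_edges() == net.n_edges
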