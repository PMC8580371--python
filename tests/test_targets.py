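"""Top-percent score filter, bipartite construction, degree reports and
enrichment statistics."""

import numpy as np
import pandas as pd
import pytest

from evmirnet import targets


def de_table(n_up, n_down):
    return pd.DataFrame(
        {
            "transcript": [f"U{i}" for i in range(n_up)] + [f"D{i}" for i in range(n_down)],
            "log2fc": [1.0] * n_up + [-1.0] * n_down,
            "direction": ["up"] * n_up + ["down"] * n_down,
        }
    )


def interactions(pairs, source="db", scores=None):
    return pd.DataFrame(
        {
            "mirna": [p[0] for p in pairs],
            "target": [p[1] for p in pairs],
            "source": source,
            "score": scores if scores is not None else np.nan,
        }
    )


class TestTopPercentFilter:
    def test_score_ladder_keeps_top_two_of_ten(self):
        inter = interactions([(f"m{i}", "t") for i in range(10)], scores=list(range(1, 11)))
        kept = targets.filter_top_percent(inter, 20.0)
        assert sorted(kept["score"]) == [9, 10]

    def test_pct_100_unchanged(self):
        inter = interactions([("a", "t"), ("b", "t")], scores=[1.0, 2.0])
        assert len(targets.filter_top_percent(inter, 100.0)) == 2

    def test_boundary_ties_all_retained(self):
        inter = interactions(
            [(f"m{i}", "t") for i in range(5)], scores=[5.0, 5.0, 5.0, 1.0, 1.0]
        )
        kept = targets.filter_top_percent(inter, 20.0)
        assert sorted(kept["score"]) == [5.0, 5.0, 5.0]

    def test_unscored_records_spared(self):
        inter = interactions(
            [(f"m{i}", "t") for i in range(4)], scores=[10.0, 1.0, np.nan, np.nan]
        )
        kept = targets.filter_top_percent(inter, 25.0)
        assert len(kept) == 3  # top scored + both unscored
        assert kept["score"].isna().sum() == 2

    def test_per_source_ranking(self):
        inter = pd.DataFrame(
            {
                "mirna": ["a", "b", "c", "d"],
                "target": ["t"] * 4,
                "source": ["x", "x", "y", "y"],
                "score": [10.0, 1.0, 3.0, 2.0],
            }
        )
        kept = targets.filter_top_percent(inter, 50.0)
        # each source keeps its own top half, even though y's scores are
        # globally lower than x's
        assert set(zip(kept["source"], kept["score"])) == {("x", 10.0), ("y", 3.0)}

    def test_invalid_pct_rejected(self):
        with pytest.raises(ValueError):
            targets.filter_top_percent(interactions([("a", "t")]), 0.0)


class TestBuildBipartite:
    def test_target_absent_from_de_excluded(self):
        de = de_table(2, 1)
        inter = interactions([("m1", "U0"), ("m1", "NOT_DE")])
        net = targets.build_bipartite({"m1"}, de, inter)
        assert net.has_edge("m1", "U0")
        assert "NOT_DE" not in net

    def test_empty_interactions_degree_zero_mirnas(self):
        net = targets.build_bipartite({"m1", "m2"}, de_table(2, 2), interactions([])[:0])
        assert net.number_of_edges() == 0
        assert set(net.nodes) == {"m1", "m2"}

    def test_duplicate_sources_collapse(self):
        de = de_table(1, 0)
        inter = pd.concat(
            [
                interactions([("m1", "U0")], source="db1"),
                interactions([("m1", "U0")], source="db2"),
            ]
        )
        net = targets.build_bipartite({"m1"}, de, inter)
        assert net.degree("m1") == 1

    def test_direction_filter_restricts(self):
        de = de_table(1, 1)
        inter = interactions([("m1", "U0"), ("m1", "D0")])
        up = targets.build_bipartite({"m1"}, de, inter, "up")
        both = targets.build_bipartite({"m1"}, de, inter, "both")
        assert up.degree("m1") == 1 and both.degree("m1") == 2

    def test_degree_handshake(self, rng):
        de = de_table(20, 10)
        mirnas = [f"m{i}" for i in range(15)]
        pairs = [
            (m, t)
            for m in mirnas
            for t in de["transcript"]
            if rng.random() < 0.2
        ]
        net = targets.build_bipartite(mirnas, de, interactions(pairs))
        left = sum(net.degree(m) for m in targets.mirna_nodes(net))
        right = sum(net.degree(t) for t in targets.target_nodes(net))
        assert left == right == net.number_of_edges()

    def test_idempotent_under_duplication(self, rng):
        de = de_table(10, 5)
        pairs = [("m1", "U0"), ("m1", "U3"), ("m2", "D1")]
        once = targets.build_bipartite({"m1", "m2"}, de, interactions(pairs))
        twice = targets.build_bipartite(
            {"m1", "m2"}, de, pd.concat([interactions(pairs)] * 2, ignore_index=True)
        )
        assert sorted(once.edges) == sorted(twice.edges)


class TestDegreeReport:
    def test_star(self):
        de = de_table(5, 0)
        inter = interactions([("m1", f"U{i}") for i in range(5)])
        net = targets.build_bipartite({"m1"}, de, inter)
        rep = targets.degree_report(net, "mirna", 0)
        assert rep.values.tolist() == [["m1", 5]]

    def test_min_degree_strict_cutoff(self):
        de = de_table(3, 0)
        inter = interactions([("m1", f"U{i}") for i in range(3)])
        net = targets.build_bipartite({"m1"}, de, inter)
        assert targets.degree_report(net, "mirna", 3).empty
        assert len(targets.degree_report(net, "mirna", 2)) == 1

    def test_matches_brute_force_counts(self, rng):
        de = de_table(15, 10)
        mirnas = [f"m{i}" for i in range(8)]
        pairs = list(
            {(m, t) for m in mirnas for t in de["transcript"] if rng.random() < 0.3}
        )
        net = targets.build_bipartite(mirnas, de, interactions(pairs))
        rep = targets.degree_report(net, "target", 0).set_index("node")["degree"]
        counts = {}
        for m, t in pairs:
            counts[t] = counts.get(t, 0) + 1
        assert dict(rep) == counts


class TestStudentT:
    def test_identical_groups(self):
        t, df, p = targets.student_t([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_hand_pooled_variance_case(self):
        t, df, p = targets.student_t([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-np.sqrt(1.5), abs=1e-4)  # -1.2247
        assert df == 4

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            targets.student_t([1.0, 1.0], [1.0, 1.0])

    def test_power_on_shifted_normals(self):
        rng = np.random.default_rng(0)
        hits = sum(
            targets.student_t(rng.normal(0, 1, 100), rng.normal(2, 1, 100))[2] < 1e-4
            for _ in range(20)
        )
        assert hits == 20


class TestEnrichment:
    def test_constructed_ratio_two(self):
        de = de_table(3, 3)
        pairs = [(f"m{i}", f"U{j}") for i in range(2) for j in range(3)]  # up degree 2
        pairs += [("m0", f"D{j}") for j in range(3)]  # down degree 1
        net = targets.build_bipartite({"m0", "m1"}, de, interactions(pairs))
        enr = targets.enrichment_stats(net, de)
        assert enr.ratio == pytest.approx(2.0)

    def test_up_fraction_counting(self):
        de = de_table(3, 1)
        pairs = [("m1", "U0"), ("m1", "U1"), ("m1", "U2"), ("m1", "D0")]
        net = targets.build_bipartite({"m1"}, de, interactions(pairs))
        enr = targets.enrichment_stats(net, de, min_mirna_degree=2)
        row = enr.mirna_up_fraction.set_index("mirna").loc["m1"]
        assert row["up_fraction"] == pytest.approx(0.75)
        assert enr.mean_up_fraction == pytest.approx(0.75)

    def test_min_mirna_degree_strict(self):
        de = de_table(2, 0)
        pairs = [("m1", "U0"), ("m1", "U1")]  # degree 2: not > 2, excluded
        net = targets.build_bipartite({"m1"}, de, interactions(pairs))
        enr = targets.enrichment_stats(net, de, min_mirna_degree=2)
        assert enr.mean_up_fraction is None

    def test_coverage(self):
        de = de_table(3, 1)
        net = targets.build_bipartite({"m1"}, de, interactions([("m1", "U0")]))
        enr = targets.enrichment_stats(net, de)
        assert enr.coverage_count == 1
        assert enr.coverage_fraction == pytest.approx(0.25)

    def test_empty_direction_flagged_degenerate(self):
        de = de_table(3, 1)
        net = targets.build_bipartite({"m1"}, de, interactions([]).iloc[:0])
        enr = targets.enrichment_stats(net, de)
        assert enr.degenerate

    def test_zero_degree_transcripts_included_by_default(self):
        de = de_table(2, 2)
        net = targets.build_bipartite({"m1"}, de, interactions([("m1", "U0"), ("m1", "D0")]))
        incl = targets.enrichment_stats(net, de)
        excl = targets.enrichment_stats(net, de, include_zero_degree=False)
        assert incl.mean_degree_up == pytest.approx(0.5)
        assert excl.mean_degree_up == pytest.approx(1.0)


class TestLabelPermutation:
    def test_extreme_observation_minimal_p(self):
        de = de_table(5, 5)
        pairs = [(f"m{i}", f"U{j}") for i in range(6) for j in range(5)]
        net = targets.build_bipartite([f"m{i}" for i in range(6)], de, interactions(pairs))
        p = targets.label_permutation_test(net, de, n_perm=99, seed=0)
        # observed difference can be tied by permutations that reproduce the
        # labelling, so p is small but bounded below by (1+1)/(99+1)
        assert p <= 5 / 100

    def test_zero_permutations_rejected(self):
        de = de_table(2, 2)
        net = targets.build_bipartite({"m"}, de, interactions([("m", "U0")]))
        with pytest.raises(ValueError):
            targets.label_permutation_test(net, de, n_perm=0)

    def test_agrees_with_t_test_on_planted_effect(self):
        from evmirnet import simulate
        from evmirnet.config import SimConfig

        cfg = SimConfig(n_up=100, n_down=60, p_base=0.05, enrichment_ratio=2.5, seed=3)
        de = simulate.simulate_de_table(cfg)
        mirnas = [f"m{i}" for i in range(40)]
        inter = simulate.simulate_interactions(mirnas, de, cfg)
        net = targets.build_bipartite(mirnas, de, inter)
        enr = targets.enrichment_stats(net, de)
        p_perm = targets.label_permutation_test(net, de, n_perm=199, seed=1)
        assert enr.p_value < 0.01 and p_perm <= 0.01
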