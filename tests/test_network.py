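"""Trajectory-network construction, outcome entropy, filtering, selections."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import cohortflow as cf
from cohortflow.network import outcome_entropy

from conftest import make_cohort


class TestBuildNetwork:
    def test_edges_follow_member_overlap_with_probabilities(self, toy_net):
        by_id = {e.id: e for e in toy_net.edges}
        probs = toy_net.probabilities
        assert set(by_id) == {"w0:0->w1:0", "w0:0->w1:1", "w0:1->w1:2"}
        assert by_id["w0:0->w1:0"].members == ("1", "2")
        assert probs["w0:0->w1:0"] == pytest.approx(2 / 3)
        assert probs["w0:0->w1:1"] == pytest.approx(1 / 3)
        assert probs["w0:1->w1:2"] == pytest.approx(1.0)

    def test_disjoint_cohorts_yield_no_edge(self):
        w0 = cf.CohortSet(0, [make_cohort(0, ["1"])])
        w1 = cf.CohortSet(1, [make_cohort(1, ["2"])])
        assert cf.build_network([w0, w1]).edges == []

    def test_single_window_rejected(self):
        with pytest.raises(ValueError):
            cf.build_network([cf.CohortSet(0, [make_cohort(0, ["1"])])])

    def test_flow_conservation_on_synthetic_cohort(self, net1000, wtrajs1000):
        """Outgoing cardinalities per node must sum to its members present downstream;
        with every patient present in all windows, probabilities sum to 1."""
        probs = net1000.probabilities
        nodes = net1000.nodes
        for nid, cohort in nodes.items():
            out = net1000.out_edges(nid)
            if cohort.window == 2:
                assert not out
                continue
            assert sum(e.cardinality for e in out) == len(cohort)
            assert sum(probs[e.id] for e in out) == pytest.approx(1.0, abs=1e-12)
        assert not net1000.attrition_nodes()

    def test_membership_conserved_across_windows(self, net1000, wtrajs1000):
        for cs in net1000.cohort_sets:
            assert cs.n_patients == len(wtrajs1000)

    def test_round_trips_through_dict(self, toy_net):
        again = cf.CohortNetwork.from_dict(toy_net.to_dict())
        assert again.to_dict() == toy_net.to_dict()


class TestEntropy:
    def test_single_certain_outcome_is_zero(self):
        assert outcome_entropy([1.0]) == pytest.approx(0.0, abs=1e-15)

    def test_even_split_is_ln_two(self):
        assert outcome_entropy([0.5, 0.5]) == pytest.approx(math.log(2), abs=1e-12)

    def test_as_printed_mode_certain_outcome_is_minus_one(self):
        assert outcome_entropy([1.0], mode="as-printed") == pytest.approx(-1.0)

    def test_no_outgoing_edges_is_flagged_not_an_error(self, toy_net):
        ent = toy_net.entropies()
        assert ent["w1:0"] is None  # terminal window
        assert ent["w0:0"] == pytest.approx(-(2 / 3) * math.log(2 / 3) - (1 / 3) * math.log(1 / 3))

    @given(
        st.lists(st.floats(min_value=0.01, max_value=1.0), min_size=1, max_size=12).map(
            lambda xs: [x / sum(xs) for x in xs]
        )
    )
    def test_shannon_bounds_and_uniform_maximum(self, probs):
        h = outcome_entropy(probs)
        k = len(probs)
        assert -1e-12 <= h <= math.log(k) + 1e-12
        uniform = outcome_entropy([1.0 / k] * k)
        assert h <= uniform + 1e-9
        if k > 1 and max(probs) - min(probs) > 1e-6:
            assert h < uniform

    def test_zero_iff_single_outcome(self):
        assert outcome_entropy([1.0]) == 0.0
        assert outcome_entropy([0.7, 0.3]) > 0.0


class TestFilterEdges:
    def test_threshold_zero_drops_split_keeps_deterministic(self, toy_net):
        filtered = cf.filter_edges(toy_net, 0.0)
        assert {e.id for e in filtered.edges} == {"w0:1->w1:2"}
        assert len(filtered.nodes) == len(toy_net.nodes)  # nodes never deleted

    def test_infinite_threshold_is_identity(self, toy_net):
        assert cf.filter_edges(toy_net, math.inf).edges == toy_net.edges

    def test_negative_shannon_threshold_rejected(self, toy_net):
        with pytest.raises(ValueError):
            cf.filter_edges(toy_net, -0.1)

    def test_as_printed_mode_threshold(self, toy_net):
        # deterministic source scores -1; the split source -(4/9 + 1/9) = -5/9
        kept = cf.filter_edges(toy_net, -0.99, mode="as-printed")
        assert {e.id for e in kept.edges} == {"w0:1->w1:2"}

    def test_threshold_zero_matches_single_target_scan(self, net1000):
        """Brute-force per-node oracle: kept iff all of a node's members share one target."""
        filtered = cf.filter_edges(net1000, 0.0)
        kept_sources = {e.source for e in filtered.edges}
        for nid in net1000.nodes:
            out = net1000.out_edges(nid)
            if not out:
                continue
            deterministic = len(out) == 1 and out[0].cardinality == len(net1000.nodes[nid])
            assert (nid in kept_sources) == deterministic
        # and filtering is all-or-none per source
        for nid in kept_sources:
            assert len(net1000.out_edges(nid)) == len(
                [e for e in filtered.edges if e.source == nid]
            )

    def test_filtering_monotone_in_threshold(self, net1000):
        ids = lambda net: {e.id for e in net.edges}
        prev = set()
        for t in (0.0, 0.2, 0.5, 1.0, math.inf):
            cur = ids(cf.filter_edges(net1000, t))
            assert prev <= cur
            assert cur <= ids(net1000)
            prev = cur


class TestHighlightAndSummaries:
    def test_node_selection_counts_path_overlap(self, toy_net):
        hl = cf.highlight(toy_net, "w0:0")
        assert hl.node_counts["w0:0"] == 3
        assert hl.node_counts["w1:0"] == 2 and hl.node_counts["w1:1"] == 1
        assert hl.node_counts["w1:2"] == 0

    def test_edge_selection(self, toy_net):
        hl = cf.highlight(toy_net, "w0:0->w1:0")
        assert hl.patient_ids == {"1", "2"}
        assert hl.node_counts["w0:0"] == 2
        assert hl.edge_counts["w0:0->w1:1"] == 0

    def test_factor_selection_spans_all_windows(self, net1000, wtrajs1000):
        hl = cf.highlight(net1000, "HD", wtrajs=wtrajs1000)
        oracle = {
            w.patient_id for w in wtrajs1000 if any("HD" in s for s in w.window_sets)
        }
        assert hl.patient_ids == oracle
        for nid, c in net1000.nodes.items():
            assert hl.node_counts[nid] == len(oracle.intersection(c.members))
            assert hl.node_counts[nid] <= len(c)

    def test_vocabulary_factor_absent_everywhere_gives_zero_overlay(self, toy_net):
        wtrajs = [cf.WindowedTrajectory(p, [frozenset(), frozenset()]) for p in "1239"]
        hl = cf.highlight(toy_net, "SLE", wtrajs=wtrajs, vocabulary=["SLE", "HTN"])
        assert not hl.patient_ids
        assert set(hl.node_counts.values()) == {0}

    def test_unknown_selection_rejected(self, toy_net):
        with pytest.raises(KeyError):
            cf.highlight(toy_net, "nonsense")

    def test_summarize_counts_sex_and_prevalence(self, wtrajs1000):
        import pandas as pd

        ids = [w.patient_id for w in wtrajs1000[:10]]
        md = pd.DataFrame(
            {"patient_id": ids, "sex": ["F"] * 6 + ["M"] * 4, "birth_year": [1950] * 10}
        )
        out = cf.summarize(
            ids,
            wtrajs=wtrajs1000,
            metadata=md,
            index_year={pid: 2005 for pid in ids},
        )
        assert out["n"] == 10
        assert out["sex_counts"] == {"F": 6, "M": 4}
        assert out["age_at_index"]["mean"] == pytest.approx(55.0)
        assert all(0 < v <= 1 for v in out["factor_prevalence"].values())

    def test_empty_selection_gives_empty_summary(self):
        assert cf.summarize([]) == {"n": 0}

    def test_index_factor_prevalence_is_total_in_year_one_window(self, pop1000, synth_map):
        spec = cf.WindowSpec([-2190, 0, 365, 1825])  # no watching
        wtrajs = cf.partition(pop1000, spec, vocabulary=synth_map)
        ids = [w.patient_id for w in wtrajs]
        out = cf.summarize(ids, wtrajs=wtrajs)
        assert out["factor_prevalence"]["CKD"] == pytest.approx(1.0)
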