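"""Cohort extraction: frequency merging, Ochiai similarity, hierarchical clustering."""

import itertools
import math
import random

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

import cohortflow as cf
from cohortflow.clustering import ComorbidityGroup, group_by_comorbidity, label_cohort


def grp(factors, members):
    return ComorbidityGroup(frozenset(factors), tuple(members))


class TestFrequencyCluster:
    def test_threshold_splits_others_by_index_presence(self):
        groups = [
            grp({"HTN"}, [f"a{i}" for i in range(300)]),
            grp({"CKD", "HD"}, [f"b{i}" for i in range(100)]),
            grp({"DM"}, [f"c{i}" for i in range(50)]),
        ]
        cs = cf.frequency_cluster(groups, 250, index_factor="CKD")
        by_kind = {c.kind: c for c in cs.cohorts}
        assert len(by_kind["comorbidity"]) == 300
        assert len(by_kind["others-index"]) == 100
        assert len(by_kind["others-nonindex"]) == 50
        assert by_kind["others-index"].label == "others (CKD)"

    def test_zero_threshold_is_identity(self):
        groups = [grp({"HTN"}, ["a"]), grp({"DM"}, ["b", "c"])]
        cs = cf.frequency_cluster(groups, 0)
        assert sorted(len(c) for c in cs.cohorts) == [1, 2]
        assert all(c.kind == "comorbidity" and not c.partial for c in cs.cohorts)

    def test_all_below_threshold_conserves_membership(self):
        groups = [grp({"HTN"}, ["a"]), grp({"CKD"}, ["b"]), grp({"DM"}, ["c"])]
        cs = cf.frequency_cluster(groups, 10)
        assert cs.n_patients == 3
        assert {c.kind for c in cs.cohorts} <= {"others-index", "others-nonindex"}

    def test_kept_cohorts_meet_threshold(self, wtrajs1000):
        groups = group_by_comorbidity(wtrajs1000, 0)
        cs = cf.frequency_cluster(groups, 25, window=0)
        assert cs.n_patients == len(wtrajs1000)
        for c in cs.cohorts:
            if c.kind == "comorbidity":
                assert len(c) >= 25


class TestOchiai:
    @pytest.mark.parametrize(
        "s1,s2,expected",
        [
            ({"f1"}, {"f1", "f2"}, 1 / math.sqrt(2)),
            ({"f1"}, {"f1"}, 1.0),
            ({"f1"}, {"f2"}, 0.0),
            (set(), set(), 1.0),
            (set(), {"f1"}, 0.0),
        ],
    )
    def test_examples(self, s1, s2, expected):
        assert cf.ochiai(s1, s2) == pytest.approx(expected, abs=1e-12)

    def test_matches_indicator_cosine_oracle_on_all_subset_pairs(self):
        """Exhaustive check over all subset pairs of a 5-factor universe."""
        universe = ["a", "b", "c", "d", "e"]
        subsets = [
            frozenset(c)
            for r in range(6)
            for c in itertools.combinations(universe, r)
        ]
        for s1 in subsets:
            for s2 in subsets:
                v1 = np.array([f in s1 for f in universe], dtype=float)
                v2 = np.array([f in s2 for f in universe], dtype=float)
                n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
                if n1 == 0 and n2 == 0:
                    oracle = 1.0
                elif n1 == 0 or n2 == 0:
                    oracle = 0.0
                else:
                    oracle = float(v1 @ v2 / (n1 * n2))
                assert cf.ochiai(s1, s2) == pytest.approx(oracle, abs=1e-12)

    @given(
        st.sets(st.sampled_from("abcdefg"), max_size=7),
        st.sets(st.sampled_from("abcdefg"), max_size=7),
    )
    def test_symmetric_bounded_identity(self, s1, s2):
        v = cf.ochiai(s1, s2)
        assert 0.0 <= v <= 1.0
        assert v == cf.ochiai(s2, s1)
        assert (v == 1.0) == (s1 == s2)


class TestHierarchical:
    def test_k_equals_unique_count_gives_singletons(self):
        groups = [grp({"HTN"}, ["a"]), grp({"DM"}, ["b"]), grp({"SLE"}, ["c"])]
        cs = cf.hierarchical_cluster(groups, 3)
        assert sorted(len(c) for c in cs.cohorts) == [1, 1, 1]

    def test_k_one_gives_single_cohort(self):
        groups = [grp({"HTN"}, ["a"]), grp({"DM"}, ["b"])]
        cs = cf.hierarchical_cluster(groups, 1)
        assert len(cs.cohorts) == 1 and len(cs.cohorts[0]) == 2

    def test_overlapping_sets_cluster_together(self):
        """Brute force over 2-partitions: {HTN},{HTN,DM} pair beats any pairing with {SLE}."""
        groups = [grp({"HTN"}, ["a"]), grp({"HTN", "DM"}, ["b"]), grp({"SLE"}, ["c"])]
        cs = cf.hierarchical_cluster(groups, 2)
        parts = {frozenset(c.members) for c in cs.cohorts}
        assert parts == {frozenset({"a", "b"}), frozenset({"c"})}

    def test_k_out_of_range_rejected(self):
        groups = [grp({"HTN"}, ["a"])]
        with pytest.raises(ValueError):
            cf.hierarchical_cluster(groups, 2)
        with pytest.raises(ValueError):
            cf.hierarchical_cluster(groups, 0)

    def test_patients_inherit_their_combination_cluster(self):
        groups = [grp({"HTN"}, ["a1", "a2", "a3"]), grp({"HTN", "DM"}, ["b1"]), grp({"SLE"}, ["c1"])]
        cs = cf.hierarchical_cluster(groups, 2)
        big = next(c for c in cs.cohorts if "a1" in c.members)
        assert set(big.members) == {"a1", "a2", "a3", "b1"}
        assert big.common_factors == {"HTN"} and big.partial

    def test_deterministic_across_runs_and_nested(self, wtrajs1000):
        groups = group_by_comorbidity(wtrajs1000, 0)[:40]
        a = cf.hierarchical_cluster(groups, 10)
        b = cf.hierarchical_cluster(groups, 10)
        assert [c.members for c in a.cohorts] == [c.members for c in b.cohorts]
        # k-solution refines the (k-1)-solution
        for k in range(2, 12):
            fine = cf.hierarchical_cluster(groups, k)
            coarse = cf.hierarchical_cluster(groups, k - 1)
            coarse_sets = [set(c.members) for c in coarse.cohorts]
            for c in fine.cohorts:
                assert any(set(c.members) <= cs for cs in coarse_sets)

    def test_agrees_with_scipy_average_linkage_on_tie_free_case(self):
        """Independent route: scipy UPGMA over the same 1-Ochiai distances."""
        sets = [frozenset("A"), frozenset("AB"), frozenset("ABC"), frozenset("D")]
        groups = [grp(s, [f"p{i}"]) for i, s in enumerate(sets)]
        dm = np.array(
            [[1 - cf.ochiai(s1, s2) for s2 in sets] for s1 in sets]
        )
        z = linkage(squareform(dm, checks=False), method="average")
        for k in (1, 2, 3, 4):
            labels = fcluster(z, t=k, criterion="maxclust")
            scipy_parts = {
                frozenset(f"p{i}" for i in range(4) if labels[i] == lab)
                for lab in set(labels)
            }
            ours = {frozenset(c.members) for c in cf.hierarchical_cluster(groups, k).cohorts}
            assert ours == scipy_parts

    def test_membership_conserved_every_window(self, wtrajs1000):
        for l in range(3):
            groups = group_by_comorbidity(wtrajs1000, l)
            k = min(8, len(groups))
            cs = cf.hierarchical_cluster(groups, k, window=l)
            assert cs.n_patients == len(wtrajs1000)


class TestLabels:
    def test_uniform_cohort_label_is_its_combination(self):
        cs = cf.frequency_cluster([grp({"HTN"}, ["a", "b"])], 0)
        assert cs.cohorts[0].label == "HTN"

    def test_common_factor_plus_extras_gets_asterisk(self):
        cs = cf.hierarchical_cluster(
            [grp({"SLE"}, ["a"]), grp({"SLE", "HTN"}, ["b"])], 1
        )
        assert cs.cohorts[0].label == "SLE*"

    def test_no_common_factor_label_is_bare_asterisk(self):
        cs = cf.hierarchical_cluster([grp({"HTN"}, ["a"]), grp({"DM"}, ["b"])], 1)
        assert cs.cohorts[0].label == "*"

    def test_custom_label_overrides(self):
        cs = cf.frequency_cluster([grp({"HTN"}, ["a"])], 0)
        cs.cohorts[0].custom_label = "my cohort"
        assert cf.label_cohort(cs.cohorts[0]) == "my cohort"

    def test_all_empty_cohort_labelled_none(self):
        cs = cf.frequency_cluster([grp(set(), ["a", "b"])], 0)
        assert cs.cohorts[0].label == "(none)"
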