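"""Promiscuity degrees, binned distributions, rankings, and the potency scan."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pkitargets.promiscuity import (
    AnalysisError,
    bin_degree_counts,
    bin_distribution,
    build_profiles,
    count_inverted_primary,
    potency_scan,
    rank_compounds_by_nonpk_targets,
    rank_targets_by_shared_inhibitors,
)
from pkitargets.records import CuratedInteraction, PromiscuityProfile

from _util import interactions_from_manifest, target, targets_from_frame


def _inter(ck, tid, ppot=6.0):
    return CuratedInteraction(ck, tid, ppot, "ic50", 1)


def _toy_targets():
    return {
        "A": target("A", is_pk=True),
        "B": target("B", is_pk=True),
        "X": target("X"),
        "Y": target("Y"),
    }


class TestBuildProfiles:
    def test_degrees_are_set_cardinalities(self):
        inters = [_inter("c1", "A"), _inter("c1", "B"), _inter("c1", "X")]
        (p,) = build_profiles(inters, _toy_targets())
        assert (p.pk_pd, p.nonpk_pd) == (2, 1)
        assert p.pk_targets == {"A", "B"} and p.nonpk_targets == {"X"}

    def test_pk_only_compound_excluded(self):
        inters = [_inter("c1", "A"), _inter("c2", "A"), _inter("c2", "X")]
        profiles = build_profiles(inters, _toy_targets())
        assert [p.compound_key for p in profiles] == ["c2"]

    def test_unknown_target_fatal(self):
        with pytest.raises(AnalysisError, match="ZZ"):
            build_profiles([_inter("c1", "ZZ")], _toy_targets())


class TestBinning:
    def test_uniform_toy_set(self):
        degrees = [1] * 10
        dist = bin_degree_counts(degrees)
        assert dist[(1, 1)] == (10, 100.0)
        assert dist[(2, 4)] == (0, 0.0)

    def test_overlapping_bins_fatal(self):
        with pytest.raises(AnalysisError):
            bin_degree_counts([1], bins=((1, 3), (3, None)))

    def test_gap_in_bins_fatal(self):
        with pytest.raises(AnalysisError):
            bin_degree_counts([1], bins=((1, 2), (5, None)))

    @given(st.lists(st.integers(min_value=1, max_value=60), min_size=1, max_size=300))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_counts_conserve_and_percentages_sum(self, degrees):
        dist = bin_degree_counts(degrees)
        assert sum(c for c, _ in dist.values()) == len(degrees)
        assert sum(p for _, p in dist.values()) == pytest.approx(100.0, abs=0.2)

    def test_which_selector(self, toy_profiles):
        pk = bin_distribution(toy_profiles, "pk")
        nonpk = bin_distribution(toy_profiles, "nonpk")
        assert pk[(1, 1)][0] == 2 and pk[(2, 4)][0] == 1
        assert nonpk[(1, 1)][0] == 2 and nonpk[(2, 4)][0] == 1


class TestRankings:
    def test_pk_ranking_counts_shared_and_counterparts(self, toy_profiles):
        rows = rank_targets_by_shared_inhibitors(toy_profiles, "pk", k=10)
        top = rows[0]
        assert (top.target_id, top.n_shared_pkis, top.n_counterpart_targets) == (
            "A",
            2,
            2,
        )

    def test_nonpk_ranking_symmetric(self, toy_profiles):
        rows = rank_targets_by_shared_inhibitors(toy_profiles, "nonpk", k=10)
        x = next(r for r in rows if r.target_id == "X")
        assert x.n_shared_pkis == 3  # c1, c2, c3 all hit X
        assert x.n_counterpart_targets == 3  # union {A, B, T3}

    def test_compound_ranking_order(self):
        profiles = [
            PromiscuityProfile("c1", frozenset({"A"}), frozenset({"X", "Y", "Z"})),
            PromiscuityProfile("c2", frozenset({"A", "B", "C", "D", "E"}), frozenset({"X", "Y"})),
        ]
        ranked = rank_compounds_by_nonpk_targets(profiles, k=10)
        assert [p.compound_key for p in ranked] == ["c1", "c2"]

    def test_k_larger_than_set(self, toy_profiles):
        assert len(rank_compounds_by_nonpk_targets(toy_profiles, k=99)) == 3

    def test_ranking_matches_brute_force(self, catalog_small):
        _, _, target_df, manifest = catalog_small
        targets = targets_from_frame(target_df)
        inters = [
            i for i in interactions_from_manifest(manifest)
            if not targets[i.target_id].is_antitarget
        ]
        profiles = build_profiles(inters, targets)
        rows = rank_targets_by_shared_inhibitors(profiles, "pk", k=5)
        for row in rows:
            hitters = [p for p in profiles if row.target_id in p.pk_targets]
            union = set().union(*(p.nonpk_targets for p in hitters))
            assert (len(hitters), len(union)) == (
                row.n_shared_pkis,
                row.n_counterpart_targets,
            )


class TestPotencyScan:
    def test_interaction_drops_out_above_its_potency(self):
        inters = [
            _inter("c1", "A", 8.0),
            _inter("c1", "X", 5.5),
            _inter("c1", "Y", 7.5),
        ]
        rows = potency_scan(inters, _toy_targets(), thresholds=(5.0, 6.0))
        assert rows[0].unique_nonpk_targets == 2
        assert rows[1].unique_nonpk_targets == 1  # X (5.5) gone at 6

    def test_base_threshold_consistent_with_profiles(self, catalog_small):
        _, _, target_df, manifest = catalog_small
        targets = targets_from_frame(target_df)
        inters = interactions_from_manifest(manifest)
        profiles = build_profiles(inters, targets)
        (row,) = potency_scan(inters, targets, thresholds=(5.0,))
        assert row.unique_pk_targets == len(
            set().union(*(p.pk_targets for p in profiles))
        )
        assert row.unique_nonpk_targets == len(
            set().union(*(p.nonpk_targets for p in profiles))
        )


class TestInvertedPrimary:
    def test_band_membership(self):
        inters = [_inter("c1", "X", 8.1), _inter("c1", "A", 5.3)]
        n, selected = count_inverted_primary(inters, _toy_targets())
        assert n == 1 and selected == ["c1"]

    def test_dual_nanomolar_not_counted(self):
        inters = [_inter("c1", "X", 8.1), _inter("c1", "A", 7.2)]
        n, selected = count_inverted_primary(inters, _toy_targets())
        assert n == 0 and selected == []

    def test_manifest_recovery(self, catalog_small):
        """Exact recovery against a direct recount from planted potencies."""
        _, _, target_df, manifest = catalog_small
        targets = targets_from_frame(target_df)
        inters = interactions_from_manifest(manifest)
        n, selected = count_inverted_primary(inters, targets)
        expected = []
        for c in manifest.compounds:
            if not (c.expected_pk_targets and c.expected_nonpk_targets):
                continue
            pk_best = max(
                i.expected_final for i in c.interactions
                if i.expected_retained and i.is_pk
            )
            nonpk_best = max(
                i.expected_final for i in c.interactions
                if i.expected_retained and not i.is_pk and not i.is_antitarget
            )
            if nonpk_best >= 7.0 and 5.0 <= pk_best < 6.0:
                expected.append(c.compound_key)
        assert selected == sorted(expected) and n == len(expected)
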