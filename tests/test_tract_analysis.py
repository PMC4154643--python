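import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meirec.marker_map import Marker, MarkerMap
from meirec.selection_recovery import ObservedRecombinant
from meirec.tract_analysis import (
    PairClass,
    TractAnalysisError,
    analyze_observed,
    bin_pairs_by_distance,
    call_marker_states,
    classify_cis_trans,
    classify_crossover,
    classify_pair,
    co_repair_pairs,
    find_hdna_tracts,
    is_patchy,
    mismatch_spectrum,
    mismatch_type,
    score_marker_outcomes,
)

from conftest import snp


def ten_map():
    return MarkerMap(tuple(snp(i * 100) for i in range(10)), selection_sites=(50, 850))


def obs_from(mmap, tops, bottoms, event_id="e0"):
    calls = tuple(
        (m.position, t, b) for m, t, b in zip(mmap.markers, tops, bottoms)
    )
    return ObservedRecombinant(calls=calls, event_id=event_id)


def obs_states(mmap, pattern):
    """pattern chars: '1' hom P1, '2' hom P2, 'h' het (donor on top),
    'H' het (donor on bottom)."""
    tops, bottoms = [], []
    for c in pattern:
        if c == "1":
            tops.append("P1"), bottoms.append("P1")
        elif c == "2":
            tops.append("P2"), bottoms.append("P2")
        elif c == "h":
            tops.append("P2"), bottoms.append("P1")
        else:
            tops.append("P1"), bottoms.append("P2")
    return obs_from(mmap, tops, bottoms)


class TestMarkerStates:
    @pytest.mark.parametrize(
        "top,bottom,state",
        [("P1", "P2", "het"), ("P2", "P2", "hom_P2"), ("P1", "P1", "hom_P1")],
    )
    def test_state_from_strand_calls(self, top, bottom, state):
        obs = ObservedRecombinant(calls=((0, top, bottom),))
        assert call_marker_states(obs)[0] == state

    def test_all_parental_gives_zero_tracts(self):
        mmap = ten_map()
        obs = obs_states(mmap, "1111111111")
        assert find_hdna_tracts(call_marker_states(obs), mmap) == []


class TestClassifyCrossover:
    def test_opposite_flanks_is_co(self):
        mmap = ten_map()
        states = call_marker_states(obs_states(mmap, "1111hh2222"))
        assert classify_crossover(states, mmap) == "CO"

    def test_same_flanks_is_nco(self):
        mmap = ten_map()
        states = call_marker_states(obs_states(mmap, "1111hh1111"))
        assert classify_crossover(states, mmap) == "NCO"

    def test_heteroduplex_flank_raises(self):
        mmap = ten_map()
        states = call_marker_states(obs_states(mmap, "h111111111"))
        with pytest.raises(TractAnalysisError):
            classify_crossover(states, mmap)


class TestFindTracts:
    def test_single_internal_run(self):
        mmap = ten_map()
        states = call_marker_states(obs_states(mmap, "111hhhh111"))
        (tract,) = find_hdna_tracts(states, mmap)
        assert tract.positions == (300, 400, 500, 600)
        assert tract.span_min == 300.0
        assert tract.span_max == 500.0  # nearest excluded markers at 200 and 700
        assert tract.display_bounds == (250.0, 650.0)

    def test_single_marker_tract_bounds(self):
        mmap = ten_map()
        states = call_marker_states(obs_states(mmap, "1111h11111"))
        (tract,) = find_hdna_tracts(states, mmap)
        assert tract.span_min == 1.0  # SNP footprint
        assert tract.span_max == 200.0

    def test_single_indel_tract_footprint(self):
        markers = tuple(snp(i * 100) for i in range(4)) + (Marker(400, "indel", 5, "ACGTA", "A"),) + tuple(
            snp(500 + i * 100, "T", "C") for i in range(3)
        )
        mmap = MarkerMap(markers, selection_sites=(50, 650))
        states = call_marker_states(obs_states(mmap, "1111h111"))
        (tract,) = find_hdna_tracts(states, mmap)
        assert tract.span_min == 5.0

    def test_internal_single_restoration_kept_in_tract(self):
        mmap = ten_map()
        states = call_marker_states(obs_states(mmap, "111h1h1111"))
        (tract,) = find_hdna_tracts(states, mmap)
        assert tract.positions == (300, 400, 500)

    def test_two_background_markers_split_tracts(self):
        mmap = ten_map()
        states = call_marker_states(obs_states(mmap, "1h11h11111"))
        tracts = find_hdna_tracts(states, mmap)
        assert [t.positions for t in tracts] == [(100,), (400,)]

    def test_converted_markers_count_as_tract(self):
        mmap = ten_map()
        states = call_marker_states(obs_states(mmap, "111221h111"))
        (tract,) = find_hdna_tracts(states, mmap)
        assert tract.positions == (300, 400, 500, 600)


class TestOutcomes:
    def test_het_conversion_and_restoration(self):
        mmap = ten_map()
        obs = obs_states(mmap, "111h2h1111")
        states = call_marker_states(obs)
        (tract,) = find_hdna_tracts(states, mmap)
        assert score_marker_outcomes(tract) == ("unrepaired", "converted", "unrepaired")

    def test_background_between_het_is_restored(self):
        mmap = ten_map()
        states = call_marker_states(obs_states(mmap, "111h1h1111"))
        (tract,) = find_hdna_tracts(states, mmap)
        assert score_marker_outcomes(tract) == ("unrepaired", "restored", "unrepaired")

    def test_all_het_all_unrepaired(self):
        mmap = ten_map()
        states = call_marker_states(obs_states(mmap, "111hhh1111"))
        (tract,) = find_hdna_tracts(states, mmap)
        assert set(score_marker_outcomes(tract)) == {"unrepaired"}

    def test_co_tract_scored_against_nearer_flank(self):
        # P1 flank | conversion | hDNA | P2 flank: conversion scored vs left
        mmap = ten_map()
        obs = obs_states(mmap, "11122hh222")
        states = call_marker_states(obs)
        assert classify_crossover(states, mmap) == "CO"
        (tract,) = find_hdna_tracts(states, mmap)
        outcomes = score_marker_outcomes(tract)
        assert outcomes[:2] == ("converted", "converted")


class TestCisTrans:
    def test_cis_all_donor_on_one_strand(self):
        mmap = ten_map()
        obs = obs_states(mmap, "111hhh1111")
        states = call_marker_states(obs)
        (tract,) = find_hdna_tracts(states, mmap)
        score_marker_outcomes(tract)
        assert classify_cis_trans(tract, obs) == "cis"

    def test_trans_opposite_strand_runs(self):
        mmap = ten_map()
        obs = obs_states(mmap, "111hhHH111")
        states = call_marker_states(obs)
        (tract,) = find_hdna_tracts(states, mmap)
        score_marker_outcomes(tract)
        assert classify_cis_trans(tract, obs) == "trans"
        assert len(tract.donor_runs) == 2

    def test_single_marker_tract_undetermined(self):
        mmap = ten_map()
        obs = obs_states(mmap, "1111h11111")
        states = call_marker_states(obs)
        (tract,) = find_hdna_tracts(states, mmap)
        score_marker_outcomes(tract)
        assert classify_cis_trans(tract, obs) == "undetermined"


class TestPatchyAndPairs:
    @pytest.mark.parametrize(
        "outcomes,expected",
        [
            (("unrepaired", "restored", "unrepaired"), True),
            (("converted", "restored"), True),
            (("unrepaired", "unrepaired"), False),
            (("converted", "converted", "converted"), False),
        ],
    )
    def test_is_patchy(self, outcomes, expected):
        assert is_patchy(outcomes) is expected

    @pytest.mark.parametrize(
        "a,b,label",
        [
            ("converted", "converted", "co_repaired"),
            ("restored", "restored", "co_repaired"),
            ("converted", "restored", "not_co_repaired"),
            ("converted", "unrepaired", "not_co_repaired"),
            ("restored", "unrepaired", "not_co_repaired"),
            ("unrepaired", "unrepaired", "excluded"),
        ],
    )
    def test_pair_rule(self, a, b, label):
        assert classify_pair(a, b) == label

    def test_pair_partition_is_exhaustive(self):
        mmap = ten_map()
        obs = obs_states(mmap, "1h2h1h2h11")
        states = call_marker_states(obs)
        tracts = find_hdna_tracts(states, mmap)
        pairs = []
        for t in tracts:
            score_marker_outcomes(t)
            pairs.extend(co_repair_pairs(t))
        total_adjacent = sum(len(t.markers) - 1 for t in tracts)
        assert len(pairs) == total_adjacent


class TestBinning:
    def test_binning_arithmetic(self):
        pairs = [
            PairClass(10, "co_repaired"),
            PairClass(10, "co_repaired"),
            PairClass(300, "not_co_repaired"),
            PairClass(15, "excluded"),
        ]
        df = bin_pairs_by_distance(pairs, bin_edges=(21,))
        near = df[df["bin"] == "<21"].iloc[0]
        far = df[df["bin"] == ">=21"].iloc[0]
        assert (near.co_repaired, near.not_co_repaired) == (2, 0)
        assert (far.co_repaired, far.not_co_repaired) == (0, 1)

    def test_empty_pairs_give_zero_table(self):
        df = bin_pairs_by_distance([], bin_edges=(21,))
        assert df["counted"].sum() == 0

    def test_printed_count_percentages(self):
        # the published tallies: 40/42 (95%) near, 40/111 (36%) far
        pairs = (
            [PairClass(10, "co_repaired")] * 40
            + [PairClass(10, "not_co_repaired")] * 2
            + [PairClass(100, "co_repaired")] * 40
            + [PairClass(100, "not_co_repaired")] * 71
        )
        df = bin_pairs_by_distance(pairs, bin_edges=(21,))
        near = df[df["bin"] == "<21"].iloc[0]
        far = df[df["bin"] == ">=21"].iloc[0]
        assert round(near.pct_co_repaired) == 95
        assert round(far.pct_co_repaired) == 36


class TestMismatchSpectrum:
    def test_snp_ambiguous_pair(self):
        m = snp(0, "A", "G")
        assert mismatch_type(m) == "A:C|G:T"

    def test_orientation_resolves_type(self):
        m = snp(0, "A", "G")
        assert mismatch_type(m, top_parent="P1") == "A:C"
        assert mismatch_type(m, top_parent="P2") == "G:T"

    def test_indel_is_loop_of_footprint_size(self):
        m = Marker(0, "indel", 3, "ACT", "A")
        assert mismatch_type(m) == "loop3"

    def test_empty_tract_list(self, rosy_map):
        df = mismatch_spectrum([], rosy_map)
        assert df.empty

    def test_trans_tract_types_inferred(self):
        mmap = ten_map()
        obs = obs_states(mmap, "111hhHH111")
        an = analyze_observed(obs, mmap)
        df = mismatch_spectrum(an.tracts, mmap)
        # all four het markers inferable: no ambiguous entries
        assert not df["mismatch"].str.contains(r"\|").any()
        assert df["unrepaired"].sum() == 4


class TestPatternProperties:
    """Properties that must hold for arbitrary observable marker patterns."""

    @staticmethod
    def _valid(pattern: str) -> bool:
        return pattern[0] in "12" and pattern[-1] in "12"

    @given(
        st.text(alphabet="12hH", min_size=10, max_size=10).filter(
            lambda s: s[0] in "12" and s[-1] in "12"
        )
    )
    @settings(max_examples=200, derandomize=True)
    def test_pair_counts_partition(self, pattern):
        mmap = ten_map()
        obs = obs_states(mmap, pattern)
        an = analyze_observed(obs, mmap)
        n_pairs = sum(len(t.markers) - 1 for t in an.tracts)
        assert len(an.pairs) == n_pairs
        for t in an.tracts:
            assert len(t.outcomes) == len(t.markers)
            assert set(t.outcomes) <= {"converted", "restored", "unrepaired"}

    @given(
        st.text(alphabet="12hH", min_size=10, max_size=10).filter(
            lambda s: s[0] in "12" and s[-1] in "12"
        )
    )
    @settings(max_examples=200, derandomize=True)
    def test_classification_total_and_bounds_ordered(self, pattern):
        mmap = ten_map()
        obs = obs_states(mmap, pattern)
        an = analyze_observed(obs, mmap)
        assert an.co_label in ("CO", "NCO")
        for t in an.tracts:
            assert t.span_min <= t.span_max
            d0, d1 = t.display_bounds
            assert t.span_min <= d1 - d0 <= t.span_max
            assert t.cis_trans in ("cis", "trans", "undetermined")
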