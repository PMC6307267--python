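"""Amplicon analyzer: indicator filter, tally, classification, profiles."""

import numpy as np
import pytest
from Bio.Seq import reverse_complement

from bekit import (
    AlignedQuery,
    AnalysisConfig,
    SimulationTruth,
    analyze,
    classify,
    control_overlay,
    extract_indicators,
    filter_by_indicators,
    get_editor,
    global_align,
    simulate_edited_reads,
    substitution_profile,
    summarize,
    tally_unique,
    translate_frames,
)


def mutate(s, pos, base):
    out = list(s)
    out[pos] = base
    return "".join(out)


class TestIndicators:
    def test_sixty_nt_reference(self):
        ref = "ACGT" * 15
        left, right = extract_indicators(ref)
        assert (left, right) == (ref[:15], ref[45:])

    def test_thirty_nt_reference_tiles_exactly(self):
        ref = "ACGTACGTACGTACGTACGTACGTACGTAC"
        left, right = extract_indicators(ref)
        assert left + right == ref

    def test_too_short_reference(self):
        with pytest.raises(ValueError):
            extract_indicators("A" * 29)


class TestFilterByIndicators:
    REF = "GATTACAGGACCTGAACGTACGTTTGACCAGGATTACAGGAGTCCTGCATGGCATACAAT"

    def test_reference_read_is_retained_whole(self):
        left, right = extract_indicators(self.REF)
        kept, dropped = filter_by_indicators([self.REF], left, right)
        assert kept == [self.REF] and dropped == 0

    def test_one_mismatch_kept_two_dropped(self):
        left, right = extract_indicators(self.REF)
        one_mm = mutate(self.REF, 3, "C")  # REF[3] is T
        two_mm = mutate(mutate(self.REF, 3, "C"), 7, "T")  # REF[7] is G
        kept, dropped = filter_by_indicators([one_mm, two_mm], left, right)
        assert kept == [one_mm]
        assert dropped == 1

    def test_reverse_complement_read_retained_identically(self):
        left, right = extract_indicators(self.REF)
        kept, dropped = filter_by_indicators([reverse_complement(self.REF)], left, right)
        assert kept == [self.REF] and dropped == 0

    def test_trimming_to_indicator_span(self):
        left, right = extract_indicators(self.REF)
        padded = "TTTTTT" + self.REF + "AAAAAA"
        kept, _ = filter_by_indicators([padded], left, right)
        assert kept == [self.REF]

    def test_never_retains_beyond_max_mm(self):
        """Brute-force check: retained reads have per-indicator Hamming <= 1."""
        rng = np.random.default_rng(8)
        left, right = extract_indicators(self.REF)
        reads = []
        for n_mm in (0, 1, 2, 3):
            r = self.REF
            for pos in rng.choice(15, size=n_mm, replace=False):
                r = mutate(r, int(pos), {"G": "A", "A": "G", "T": "C", "C": "T"}[r[int(pos)]])
            reads.append(r)
        kept, dropped = filter_by_indicators(reads, left, right)
        for k in kept:
            mm_left = sum(1 for a, b in zip(k[:15], left) if a != b)
            mm_right = sum(1 for a, b in zip(k[-15:], right) if a != b)
            assert mm_left <= 1 and mm_right <= 1
        assert dropped == 2


class TestTallyUnique:
    def test_counting_and_order(self):
        assert tally_unique(["A", "A", "B"], 1) == [("A", 2), ("B", 1)]

    def test_min_frequency_cutoff(self):
        assert tally_unique(["A", "A", "B"], 2) == [("A", 2)]
        assert tally_unique(["A"] * 5 + ["B"] * 5 + ["C"] * 5, 6) == []

    def test_tie_broken_lexicographically(self):
        assert tally_unique(["B", "A", "B", "A"], 1) == [("A", 2), ("B", 2)]


class TestClassify:
    def test_identical_rows_are_wt(self, amplicon):
        ref = amplicon.reference
        assert classify((ref, ref), amplicon) == ("wt", False)

    def test_window_c_to_t_is_intended_substitution(self, amplicon):
        pos = next(p for p in amplicon.window_positions if amplicon.reference[p] == "C")
        query = mutate(amplicon.reference, pos, "T")
        aln = global_align(amplicon.reference, query)
        assert classify(aln, amplicon) == ("substitution", True)

    def test_non_substrate_window_change_is_unintended(self, amplicon):
        pos = next(p for p in amplicon.window_positions if amplicon.reference[p] != "C")
        alt = {"A": "G", "G": "A", "T": "A"}[amplicon.reference[pos]]
        aln = global_align(amplicon.reference, mutate(amplicon.reference, pos, alt))
        assert classify(aln, amplicon) == ("substitution", False)

    def test_gap_in_ref_row_is_insertion(self, amplicon):
        pos = amplicon.window_positions[0]
        query = amplicon.reference[:pos] + "A" * 2 + amplicon.reference[pos:]
        aln = global_align(amplicon.reference, query)
        assert aln.ref_row.count("-") == 2
        assert classify(aln, amplicon) == ("insertion", False)

    def test_gap_in_query_row_is_deletion(self, amplicon):
        pos = amplicon.window_positions[0]
        query = amplicon.reference[:pos] + amplicon.reference[pos + 3 :]
        aln = global_align(amplicon.reference, query)
        assert classify(aln, amplicon) == ("deletion", False)

    def test_variation_outside_scope_is_wt(self, amplicon):
        lo, hi = amplicon.scope_span
        far = hi + 20
        assert far < len(amplicon.reference) - 15
        alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[amplicon.reference[far]]
        aln = global_align(amplicon.reference, mutate(amplicon.reference, far, alt))
        assert classify(aln, amplicon) == ("wt", False)

    def test_hyphen_rule_example(self, amplicon):
        """An explicit alignment with one extra query base inside the scope."""
        lo, _ = amplicon.scope_span
        ref = amplicon.reference
        ref_row = ref[: lo + 1] + "-" + ref[lo + 1 :]
        query_row = ref[: lo + 1] + "A" + ref[lo + 1 :]
        assert classify((ref_row, query_row), amplicon) == ("insertion", False)


class TestSummarize:
    def make_aq(self, label, count, intended=False):
        return AlignedQuery("A", "A", count, label, intended)

    def test_all_wt(self):
        s = summarize([self.make_aq("wt", 10)], 10, 10)
        assert s.wt == 10 and s.intended_rate == 0.0
        assert s.insertions == s.deletions == s.with_substitution == 0

    def test_intended_rate(self):
        aligned = [
            self.make_aq("substitution", 6, intended=True),
            self.make_aq("wt", 4),
        ]
        s = summarize(aligned, 12, 11)
        assert s.above_min_frequency == 10
        assert s.intended_rate == 0.6
        assert s.total_sequences == 12 and s.with_both_indicators == 11

    def test_conservation_and_field_count(self):
        aligned = [
            self.make_aq("wt", 3),
            self.make_aq("insertion", 2),
            self.make_aq("deletion", 4),
            self.make_aq("substitution", 1),
        ]
        s = summarize(aligned, 10, 10)
        assert s.wt + s.insertions + s.deletions + s.with_substitution == s.above_min_frequency
        assert len(s.to_dict()) == 9

    def test_no_reads_is_an_error(self):
        with pytest.raises(ValueError, match="no analyzable reads"):
            summarize([], 5, 0)


class TestSubstitutionProfile:
    def test_single_c_to_t_read(self, amplicon):
        pos = next(p for p in amplicon.window_positions if amplicon.reference[p] == "C")
        aln = global_align(amplicon.reference, mutate(amplicon.reference, pos, "T"))
        aq = AlignedQuery(aln.ref_row, aln.query_row, 8, "substitution", True)
        prof = substitution_profile([aq], amplicon)
        i = prof.positions.index(pos)
        assert prof.base_percent[i]["T"] == 100.0
        assert prof.transition_rate[i]["C>T"] == 1.0
        assert prof.coverage[i] == 8

    def test_weighted_transition_split(self, amplicon):
        pos = next(p for p in amplicon.window_positions if amplicon.reference[p] == "C")
        a1 = global_align(amplicon.reference, mutate(amplicon.reference, pos, "T"))
        a2 = global_align(amplicon.reference, mutate(amplicon.reference, pos, "G"))
        aqs = [
            AlignedQuery(a1.ref_row, a1.query_row, 3, "substitution", True),
            AlignedQuery(a2.ref_row, a2.query_row, 1, "substitution", True),
        ]
        prof = substitution_profile(aqs, amplicon)
        i = prof.positions.index(pos)
        assert prof.transition_rate[i]["C>T"] == 0.75
        assert prof.transition_rate[i]["C>G"] == 0.25

    def test_base_percentages_sum_to_100(self, amplicon):
        truth = SimulationTruth(
            n_reads=150, seed=4,
            intended=((amplicon.window_positions[2], 0.4, "T"),),
            error_rate=0.01,
        )
        reads, _ = simulate_edited_reads(amplicon, truth)
        result = analyze(reads, amplicon)
        for bp in result.profile.base_percent:
            assert sum(bp.values()) == pytest.approx(100.0, abs=0.01)

    def test_no_substitution_reads_flags_empty(self, amplicon):
        prof = substitution_profile([], amplicon)
        assert prof.empty
        for i, b in enumerate(prof.ref_bases):
            assert prof.base_percent[i][b] == 100.0


@pytest.mark.parametrize(
    "seq,frame,expected",
    [("ATGAAA", 0, "MK"), ("TATGAAA", 1, "MK"), ("TAA", 0, "*")],
)
def test_translate_frames(seq, frame, expected):
    assert translate_frames(seq)[frame] == expected


def test_translate_frames_drops_partial_codons():
    frames = translate_frames("ATGAAAT")
    assert frames[0] == "MK"  # trailing T dropped
    assert set(frames) == {0, 1, 2}


class TestControlOverlay:
    def test_zero_control_leaves_profile_unflagged(self, amplicon):
        pos = next(p for p in amplicon.window_positions if amplicon.reference[p] == "C")
        aln = global_align(amplicon.reference, mutate(amplicon.reference, pos, "T"))
        aq = AlignedQuery(aln.ref_row, aln.query_row, 5, "substitution", True)
        treated = substitution_profile([aq], amplicon)
        control = substitution_profile([], amplicon)
        out = control_overlay(treated, control)
        assert not any(out.background)
        assert all(v == 0.0 for cr in out.control_rate for v in cr.values())
        assert out.transition_rate == treated.transition_rate

    def test_equal_rate_is_background_and_low_rate_is_not(self, amplicon):
        pos = next(p for p in amplicon.window_positions if amplicon.reference[p] == "C")
        t_aln = global_align(amplicon.reference, mutate(amplicon.reference, pos, "T"))
        sub = AlignedQuery(t_aln.ref_row, t_aln.query_row, 30, "substitution", True)
        wt_aln = global_align(amplicon.reference, amplicon.reference)
        # control at the same 0.30 rate -> background; control at 0.02 -> not
        treated = substitution_profile(
            [sub, AlignedQuery(wt_aln.ref_row, wt_aln.query_row, 70, "substitution", False)],
            amplicon,
        )
        same = control_overlay(treated, treated)
        i = treated.positions.index(pos)
        assert same.background[i]
        low_ctrl = substitution_profile(
            [AlignedQuery(t_aln.ref_row, t_aln.query_row, 2, "substitution", True),
             AlignedQuery(wt_aln.ref_row, wt_aln.query_row, 98, "substitution", False)],
            amplicon,
        )
        out = control_overlay(treated, low_ctrl)
        assert not out.background[i]
        assert out.control_rate[i]["C>T"] == pytest.approx(-0.02)

    def test_position_mismatch_is_an_error(self, amplicon, be3):
        treated = substitution_profile([], amplicon)
        other = AnalysisConfig(
            reference=amplicon.reference, target_site=amplicon.target_site,
            editor=be3, flank_left=2, flank_right=2,
        )
        control = substitution_profile([], other)
        with pytest.raises(ValueError):
            control_overlay(treated, control)


class TestEndToEnd:
    def test_clean_wt_run(self, amplicon):
        truth = SimulationTruth(n_reads=50, seed=1)
        reads, _ = simulate_edited_reads(amplicon, truth)
        result = analyze(reads, amplicon)
        s = result.summary
        assert s.wt == 50 and s.intended_rate == 0.0
        assert s.total_sequences == s.with_both_indicators == 50

    def test_matches_simulator_truth_exactly_at_zero_error(self, amplicon):
        # flanks wide enough that the nominal cut site is inside the
        # variant-call scope, so simulated indels are classified as such
        config = AnalysisConfig(
            reference=amplicon.reference, target_site=amplicon.target_site,
            editor=amplicon.editor, flank_left=5, flank_right=15,
        )
        pos = next(p for p in config.window_positions if config.reference[p] == "C")
        truth = SimulationTruth(
            n_reads=400, seed=9,
            intended=((pos, 0.3, "T"),),
            indel_prob=0.1,
        )
        reads, labels = simulate_edited_reads(config, truth)
        result = analyze(reads, config)
        expected = {"wt": 0, "insertion": 0, "deletion": 0, "substitution": 0}
        for lb in labels:
            expected[lb.expected_label] += 1
        s = result.summary
        assert (s.wt, s.insertions, s.deletions, s.with_substitution) == (
            expected["wt"], expected["insertion"], expected["deletion"],
            expected["substitution"],
        )
        assert s.intended_in_window == sum(
            1 for lb in labels if lb.expected_label == "substitution" and lb.intended_edited
        )
        assert s.wt + s.insertions + s.deletions + s.with_substitution == s.above_min_frequency

    def test_min_frequency_discards_rare_sequences(self, amplicon):
        ref = amplicon.reference
        pos = amplicon.window_positions[0]
        alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[ref[pos]]
        reads = [ref] * 10 + [mutate(ref, pos, alt)] * 2
        config = AnalysisConfig(
            reference=ref, target_site=amplicon.target_site, editor=amplicon.editor,
            flank_left=5, flank_right=5, min_frequency=3,
        )
        result = analyze(reads, config)
        assert result.summary.above_min_frequency == 10
        assert result.summary.wt == 10
        assert result.drop_counts["below_min_frequency"] == 2

    def test_determinism(self, amplicon):
        truth = SimulationTruth(
            n_reads=100, seed=2,
            intended=((amplicon.window_positions[2], 0.3, "T"),), indel_prob=0.05,
        )
        reads, _ = simulate_edited_reads(amplicon, truth)
        r1 = analyze(reads, amplicon)
        r2 = analyze(reads, amplicon)
        assert r1 == r2
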