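"""Framework scanner, classifier, connectivity, identity and composition."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from crpforge import (
    SequenceRecord,
    assign_connectivity,
    classify_8c_hlp,
    compute_composition,
    pairwise_identity,
    scan_crp_motif,
)
from crpforge.motif import DEFAULT_LOOP_BOUNDS, MotifMatch


def brute_force_scan(seq: str, bounds=DEFAULT_LOOP_BOUNDS):
    """Independent oracle: enumerate all 8-subsets of cysteine positions,
    keep those with cysteine-free loops satisfying the bounds, then apply
    the same greedy left-to-right non-sharing resolution."""
    cys = [i for i, ch in enumerate(seq) if ch == "C"]
    candidates = []
    for subset in itertools.combinations(cys, 8):
        gaps = [subset[k + 1] - subset[k] - 1 for k in range(7)]
        loops = [seq[subset[k] + 1 : subset[k + 1]] for k in range(7)]
        if any("C" in lp for lp in loops):
            continue
        if all(lo <= g <= hi for g, (lo, hi) in zip(gaps, bounds)):
            candidates.append(subset)
    chosen, used = [], set()
    for subset in sorted(candidates):
        if not used.intersection(subset):
            chosen.append(tuple(p + 1 for p in subset))
            used.update(subset)
    return chosen


class TestScanner:
    def test_tc1_single_match_positions_and_loops(self, tc1_match):
        assert tc1_match.cys_positions == (1, 8, 15, 16, 19, 21, 28, 33)
        assert tc1_match.loop_lengths == (6, 6, 0, 2, 1, 6, 4)

    def test_bare_cysteine_run_rejected(self):
        rec = SequenceRecord(id="cc", seq="CCCCCCCC", kind="protein")
        assert scan_crp_motif(rec) == []

    def test_requires_protein_record(self):
        with pytest.raises(ValueError):
            scan_crp_motif(SequenceRecord(id="n", seq="ACGT", kind="nucleotide"))

    def test_no_cysteines_no_match(self):
        rec = SequenceRecord(id="x", seq="GAVLIMFW" * 5, kind="protein")
        assert scan_crp_motif(rec) == []

    def test_ambiguous_loop_flagged_low_confidence(self, tc1_record):
        seq = tc1_record.seq.replace("L", "X", 1)
        matches = scan_crp_motif(SequenceRecord(id="x", seq=seq, kind="protein"))
        assert len(matches) == 1 and matches[0].low_confidence

    @settings(deadline=None, max_examples=300)
    @given(st.text(alphabet="CA", min_size=1, max_size=40))
    def test_matches_brute_force_oracle_on_reduced_alphabet(self, seq):
        rec = SequenceRecord(id="h", seq=seq, kind="protein")
        got = [m.cys_positions for m in scan_crp_motif(rec)]
        assert got == brute_force_scan(seq)

    @settings(deadline=None, max_examples=100)
    @given(st.text(alphabet="CGASMFNY", min_size=1, max_size=200))
    def test_matches_brute_force_oracle_on_random_proteins(self, seq):
        rec = SequenceRecord(id="h", seq=seq, kind="protein")
        got = [m.cys_positions for m in scan_crp_motif(rec)]
        assert got == brute_force_scan(seq)

    def test_matches_do_not_share_cysteines(self, tc1_record):
        two = tc1_record.seq + "GG" + tc1_record.seq
        matches = scan_crp_motif(SequenceRecord(id="2x", seq=two, kind="protein"))
        assert len(matches) == 2
        flat = [p for m in matches for p in m.cys_positions]
        assert len(flat) == len(set(flat))


def _shifted_match(loops, offset=0, source="built"):
    """Construct a MotifMatch from loop strings at an arbitrary offset."""
    seq = "A" * offset + "C" + "C".join(loops) + "C"
    positions = []
    pos = offset + 1
    positions.append(pos)
    for lp in loops:
        pos += len(lp) + 1
        positions.append(pos)
    return MotifMatch(
        source_id=source,
        cys_positions=tuple(positions),
        loops=tuple(loops),
        span=(positions[0], positions[-1]),
    )


class TestClassifier:
    def test_tc1_is_ginsentide_like(self, tc1_match):
        cls = classify_8c_hlp(tc1_match)
        assert cls.label == "ginsentide_like"
        assert cls.evidence

    def test_chitin_binding_rule(self):
        match = _shifted_match(["AAG", "GGS", "", "ASYGY", "AAYAAA", "GGG", "GG"])
        cls = classify_8c_hlp(match)
        assert cls.label == "chitin_binding_8C_HLP"
        assert set(cls.evidence) == {"sxfxf_loop3", "aromatic_loop4_len6"}

    def test_neither_rule_gives_other(self):
        match = _shifted_match(["AAG", "GGS", "", "GGA", "AAA", "GGG", "GG"])
        cls = classify_8c_hlp(match)
        assert cls.label == "other_8C" and cls.evidence == []

    def test_classification_is_position_shift_invariant(self):
        loops = ["LSAGGF", "MFNPMD", "", "GN", "G", "LYPMGI", "YGSG"]
        assert (
            classify_8c_hlp(_shifted_match(loops)).label
            == classify_8c_hlp(_shifted_match(loops, offset=17)).label
            == "ginsentide_like"
        )


class TestConnectivity:
    def test_tc1_pairs(self, tc1_match):
        pairs = assign_connectivity(tc1_match)
        assert [p.positions for p in pairs] == [(1, 16), (8, 21), (15, 28), (19, 33)]
        assert [p.roman_pair for p in pairs] == ["I-IV", "II-VI", "III-VII", "V-VIII"]

    def test_pairs_partition_all_eight_cysteines(self, tc1_match):
        pairs = assign_connectivity(tc1_match)
        flat = sorted(p for pair in pairs for p in pair.positions)
        assert flat == sorted(tc1_match.cys_positions)

    def test_offset_shifts_positions_not_pattern(self):
        loops = ["LSAGGF", "MFNPMD", "", "GN", "G", "LYPMGI", "YGSG"]
        base = assign_connectivity(_shifted_match(loops))
        moved = assign_connectivity(_shifted_match(loops, offset=10))
        assert [p.roman_pair for p in base] == [p.roman_pair for p in moved]
        for b, m in zip(base, moved):
            assert (m.positions[0] - b.positions[0], m.positions[1] - b.positions[1]) == (10, 10)


class TestIdentity:
    def test_identical_sequences(self, tc1_record):
        assert pairwise_identity(tc1_record.seq, tc1_record.seq) == 100.0

    @pytest.mark.parametrize("n_diffs, expected", [(1, 96.97), (2, 93.94)])
    def test_point_differences_on_33mers(self, tc1_record, n_diffs, expected):
        other = list(tc1_record.seq)
        for i, pos in enumerate([2, 4][:n_diffs]):
            other[pos] = "W" if other[pos] != "W" else "H"
        val = pairwise_identity(tc1_record.seq, "".join(other))
        assert val == pytest.approx(expected, abs=0.01)

    def test_symmetry_with_gapped_alignment(self):
        a, b = "CLSAGGFCMFNP", "CLSAGFCMFNP"  # one deletion
        assert pairwise_identity(a, b) == pytest.approx(pairwise_identity(b, a))
        assert 80 < pairwise_identity(a, b) < 100

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "A")


class TestComposition:
    def test_tc1_counts_and_percents(self, tc1_record):
        comp = compute_composition(tc1_record.seq)
        assert comp.length == 33
        assert comp.counts["C"] == 8 and comp.counts["G"] == 7 and comp.counts["M"] == 3
        assert comp.percents["C"] == 24.2 and comp.percents["G"] == 21.2

    def test_tc1_net_charge_negative_one(self, tc1_record):
        assert compute_composition(tc1_record.seq).net_formal_charge == -1

    def test_single_residue(self):
        comp = compute_composition("G")
        assert comp.length == 1 and comp.percents["G"] == 100.0

    def test_non_canonical_residue_reports_positions(self):
        with pytest.raises(ValueError, match="2"):
            compute_composition("GXG")

    @settings(deadline=None)
    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=80))
    def test_percents_sum_to_100(self, seq):
        comp = compute_composition(seq)
        assert sum(comp.counts.values()) == comp.length
        assert sum(comp.percents.values()) == pytest.approx(100.0, abs=0.1 * len(comp.percents))
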