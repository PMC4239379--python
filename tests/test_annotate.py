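"""Structural annotation: PAST regions, glycomodules, cysteine motif, rule."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from xylptools.annotate import (
    CysPatternSpec,
    annotate_family,
    classify_xylp,
    clade_a_spec,
    clade_c_spec,
    default_specs,
    find_past_regions,
    generic_spec,
    match_cys_pattern,
    scan_glycomodules,
    widen_gap_sets,
)
from xylptools.io import AnnotationFlags, ProteinRecord


def _regions(record, window=50, threshold=0.35):
    return [(r.start, r.end, r.score)
            for r in find_past_regions(record, window, threshold)]


class TestPastRegions:
    def test_all_past_sequence_is_one_full_region(self):
        rec = ProteinRecord("g", "APSTAPSTAPST")
        assert _regions(rec, window=10) == [(1, 12, 1.0)]

    def test_no_past_residues_no_regions(self):
        assert _regions(ProteinRecord("g", "GGGGGGGGGG")) == []

    def test_threshold_is_strict(self):
        # window fraction exactly at the threshold must not qualify
        rec = ProteinRecord("g", "APSTAPSGGGGGGGGGGGGG")  # 7/20 = 0.35
        assert _regions(rec, window=20, threshold=0.35) == []

    def test_matches_bruteforce_window_oracle(self):
        rng = np.random.default_rng(7)
        letters = np.array(list("PASTGLIVCKRDEQNFWYHM"))
        for _ in range(50):
            n = int(rng.integers(5, 150))
            seq = "".join(rng.choice(letters, size=n))
            rec = ProteinRecord("g", seq)
            for window in (10, 20, 50):
                got = _regions(rec, window=window)
                want = oracles.past_regions_bruteforce(seq, window, 0.35)
                assert [(s, e) for s, e, _ in got] == [(s, e) for s, e, _ in want]
                for (_, _, a), (_, _, b) in zip(got, want):
                    assert a == pytest.approx(b)

    def test_planted_block_with_flanks(self):
        # PAST only at positions 41..80 of a 100-residue sequence
        seq = "G" * 40 + "PAST" * 10 + "G" * 20
        got = _regions(ProteinRecord("g", seq), window=20)
        want = oracles.past_regions_bruteforce(seq, 20, 0.35)
        assert [(s, e) for s, e, _ in got] == [(s, e) for s, e, _ in want]

    def test_score_equals_recomputed_past_fraction(self):
        rec = ProteinRecord("g", "G" * 30 + "APSTAPSTAPSTAPSTAPST" + "G" * 30)
        for r in find_past_regions(rec, window=20):
            seg = rec.sequence[r.start - 1:r.end]
            assert r.score == pytest.approx(
                sum(c in "PAST" for c in seg) / len(seg))


class TestGlycomodules:
    def test_short_sequences_have_no_hits(self):
        assert scan_glycomodules(ProteinRecord("g", "G"),
                                 restrict_to_past=False) == []

    def test_back_to_back_hits(self):
        hits = scan_glycomodules(ProteinRecord("g", "APAPSPTP"),
                                 dipeptide_set=("AP", "PA", "SP", "TP"),
                                 restrict_to_past=False)
        assert [(h.position, h.dipeptide) for h in hits] == [
            (1, "AP"), (3, "AP"), (5, "SP"), (7, "TP")]

    def test_leftmost_hit_suppresses_overlap(self):
        hits = scan_glycomodules(ProteinRecord("g", "PAP"),
                                 dipeptide_set=("PA", "AP"),
                                 restrict_to_past=False)
        assert [(h.position, h.dipeptide) for h in hits] == [(1, "PA")]

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(3)
        letters = np.array(list("PASTGV"))
        for _ in range(100):
            seq = "".join(rng.choice(letters, size=int(rng.integers(2, 80))))
            got = scan_glycomodules(ProteinRecord("g", seq),
                                    restrict_to_past=False)
            want = oracles.glycomodules_bruteforce(
                seq, {"AP", "PA", "SP", "TP", "GP", "VP"})
            assert [(h.position, h.dipeptide) for h in got] == want

    def test_restriction_to_past_never_adds_hits(self):
        rng = np.random.default_rng(5)
        letters = np.array(list("PASTGLIVKRDEQN"))
        for _ in range(50):
            seq = "".join(rng.choice(letters, size=int(rng.integers(10, 200))))
            rec = ProteinRecord("g", seq)
            unrestricted = scan_glycomodules(rec, restrict_to_past=False)
            restricted = scan_glycomodules(rec, restrict_to_past=True)
            assert len(restricted) <= len(unrestricted)


def _clade_a_sequence(g=(9, 16, 12, 22, 7), h="L"):
    return ("C" + "A" * g[0] + "C" + "A" * g[1] + "CC" + "A" * g[2] +
            "C" + h + "C" + "A" * g[3] + "C" + "A" * g[4] + "C")


class TestCysPattern:
    def test_clade_a_worked_example(self):
        rec = ProteinRecord("g", _clade_a_sequence())
        m = match_cys_pattern(rec, clade_a_spec())
        assert m is not None
        assert m.gaps == (9, 16, 12, 22, 7)
        assert m.hydrophobic_residue == "L"
        assert m.cys_positions[0] == 1 and m.cys_positions[-1] == len(rec)

    def test_seven_cysteines_never_match(self):
        seq = _clade_a_sequence()[:-1] + "A"  # drop the eighth cysteine
        rec = ProteinRecord("g", seq)
        for spec in default_specs():
            assert match_cys_pattern(rec, spec) is None

    def test_gap_outside_set_rejected(self):
        rec = ProteinRecord("g", _clade_a_sequence(g=(11, 16, 12, 22, 7)))
        assert match_cys_pattern(rec, clade_a_spec()) is None

    def test_widened_gap_sets_accept_in_between_values(self):
        rec = ProteinRecord("g", _clade_a_sequence(g=(9, 16, 13, 22, 7)))
        assert match_cys_pattern(rec, clade_a_spec()) is None  # 13 not in {12,14}
        assert match_cys_pattern(rec, widen_gap_sets(clade_a_spec())) is not None

    def test_internal_cysteine_in_gap_blocks_match_by_default(self):
        g = (9, 16, 12, 22, 7)
        seq = ("C" + "A" * 4 + "C" + "A" * 4 + "C" + "A" * g[1] + "CC" +
               "A" * g[2] + "CLC" + "A" * g[3] + "C" + "A" * g[4] + "C")
        rec = ProteinRecord("g", seq)
        spec = CysPatternSpec("x", (frozenset({9}),) + clade_a_spec().gap_sets[1:],
                              frozenset("LVI"), None)
        assert match_cys_pattern(rec, spec) is None
        assert match_cys_pattern(rec, spec, allow_internal_cys=True) is not None

    @pytest.mark.parametrize("spec_factory", [clade_a_spec, clade_c_spec,
                                              generic_spec])
    def test_agrees_with_regex_oracle_on_random_sequences(self, spec_factory):
        spec = spec_factory()
        rng = np.random.default_rng(17)
        letters = np.array(list("CCCALIVGSTPKRDE"))  # cysteine-enriched
        for _ in range(500):
            seq = "".join(rng.choice(letters, size=int(rng.integers(20, 150))))
            got = match_cys_pattern(ProteinRecord("g", seq), spec)
            want = oracles.regex_motif_start(seq, spec)
            assert (got.start if got else None) == want

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.text(alphabet="CALIVGSTP", min_size=10, max_size=120))
    def test_agrees_with_regex_oracle_property(self, seq):
        rec = ProteinRecord("g", seq) if seq.strip() else None
        if rec is None:
            return
        for spec in default_specs():
            got = match_cys_pattern(rec, spec)
            assert (got.start if got else None) == oracles.regex_motif_start(
                seq, spec)


class TestClassification:
    def test_planted_members_and_decoys(self, small_family):
        specs = [clade_a_spec(), clade_c_spec()]
        anns = annotate_family(small_family.records, small_family.flags, specs)
        for a in anns:
            truth = small_family.truth[a.protein_id]
            assert a.is_xylp == truth["is_xylp"], a.protein_id
            if truth["is_xylp"]:
                assert a.clade_hypothesis == truth["clade"]

    def test_signal_flag_is_required(self, small_family):
        rec = next(r for r in small_family.records
                   if small_family.truth[r.id]["is_xylp"])
        no_signal = AnnotationFlags(rec.id, False, True, ())
        ann = classify_xylp(rec, no_signal, [clade_a_spec(), clade_c_spec()])
        assert not ann.is_xylp

    def test_glycomodules_are_required(self, small_family):
        decoy = next(r for r in small_family.records
                     if small_family.truth[r.id]["decoy_class"] == "no_glycomodules")
        ann = classify_xylp(decoy, small_family.flags[decoy.id],
                            [clade_a_spec(), clade_c_spec()])
        assert ann.nsltp_match is not None and len(ann.glycomodules) == 0
        assert not ann.is_xylp

    def test_gpi_flag_not_required(self, small_family):
        rec = next(r for r in small_family.records
                   if small_family.truth[r.id]["is_xylp"])
        no_gpi = AnnotationFlags(rec.id, True, False, ())
        ann = classify_xylp(rec, no_gpi, [clade_a_spec(), clade_c_spec()])
        assert ann.is_xylp

    def test_missing_flags_row_names_protein(self, small_family):
        with pytest.raises(KeyError, match=small_family.records[0].id):
            annotate_family(small_family.records, {}, default_specs())
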