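"""Sequence annotation: FASTA I/O, alignment, site extraction, subtype rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from furkit.seq_annotation import (
    GAP,
    AlignmentResult,
    ProteinRecord,
    ReferenceScheme,
    SequenceError,
    SiteProfile,
    Subtype,
    classify_subtype,
    extinction_coefficient_280,
    extract_site_profile,
    find_cxxc,
    global_align,
    identity_matrix,
    map_positions,
    percent_identity,
    read_fasta,
)

from conftest import gotoh_score

AA20 = "ACDEFGHIKLMNPQRSTVWY"
sequences = st.text(alphabet=AA20, min_size=1, max_size=40)


class TestReadFasta:
    def test_single_record(self, write_fasta_file):
        recs = read_fasta(write_fasta_file(">a\nMKH\n"))
        assert len(recs) == 1
        assert recs[0].id == "a" and recs[0].sequence == "MKH"

    def test_two_records_order_preserved(self, write_fasta_file):
        recs = read_fasta(write_fasta_file(">b\nMK\n>a\nGG\n"))
        assert [r.id for r in recs] == ["b", "a"]

    def test_illegal_residue_rejected(self, write_fasta_file):
        with pytest.raises(SequenceError, match="illegal residue"):
            read_fasta(write_fasta_file(">a\nMKJ\n"))

    def test_x_allowed_only_on_request(self, write_fasta_file):
        path = write_fasta_file(">a\nMKX\n")
        with pytest.raises(SequenceError):
            read_fasta(path)
        assert read_fasta(path, allow_x=True)[0].sequence == "MKX"

    def test_empty_file_rejected(self, write_fasta_file):
        with pytest.raises(SequenceError, match="no FASTA records"):
            read_fasta(write_fasta_file(""))

    def test_duplicate_ids_rejected(self, write_fasta_file):
        with pytest.raises(SequenceError, match="duplicate"):
            read_fasta(write_fasta_file(">a\nMK\n>a\nGG\n"))


class TestGlobalAlign:
    def test_self_alignment_is_gapless_full_match(self):
        rec = ProteinRecord("x", "MKHLWDERT")
        aln = global_align(rec, rec)
        assert aln.matches == len(rec) == aln.aligned_length
        assert "-" not in aln.aligned_a

    def test_score_equals_affine_dp_oracle_on_fixed_example(self):
        a, b = ProteinRecord("a", "HEAGAWGHEE"), ProteinRecord("b", "PAWHEAE")
        aln = global_align(a, b)
        assert aln.score == pytest.approx(gotoh_score(a.sequence, b.sequence))
        assert aln.score == pytest.approx(4.0)  # frozen from the oracle

    def test_score_equals_affine_dp_oracle_randomized(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            la, lb = rng.integers(1, 13, size=2)
            a = "".join(rng.choice(list(AA20), la))
            b = "".join(rng.choice(list(AA20), lb))
            aln = global_align(ProteinRecord("a", a), ProteinRecord("b", b))
            assert aln.score == pytest.approx(gotoh_score(a, b)), (a, b)

    def test_degapping_recovers_inputs(self):
        a, b = ProteinRecord("a", "MKWWHDE"), ProteinRecord("b", "MWHE")
        aln = global_align(a, b)
        assert aln.aligned_a.replace("-", "") == a.sequence
        assert aln.aligned_b.replace("-", "") == b.sequence


class TestPercentIdentity:
    def test_identical_sequences_give_100(self):
        rec = ProteinRecord("x", "MKHLW")
        assert percent_identity(global_align(rec, rec)) == 100.0

    def test_half_matching_gapless_pair(self):
        aln = global_align(ProteinRecord("a", "AAAA"), ProteinRecord("b", "AATT"))
        assert aln.aligned_length == 4
        assert percent_identity(aln) == 50.0

    def test_symmetric_in_arguments(self):
        a, b = ProteinRecord("a", "MKWWHDERT"), ProteinRecord("b", "MWHERTGG")
        assert percent_identity(global_align(a, b)) == pytest.approx(
            percent_identity(global_align(b, a))
        )


class TestMapPositions:
    def test_gapless_equal_length_is_identity_map(self, scheme):
        ref = scheme.reference
        target = ref.sequence[:-1] + "A"
        aln = AlignmentResult(ref.sequence, target, 149, 150, 0.0)
        mapping = map_positions(aln, scheme)
        for p in scheme.all_positions:
            assert mapping[p] == (p, target[p - 1])

    def test_reference_position_opposite_gap(self, scheme):
        ref = scheme.reference.sequence
        # delete target residue at reference position 37
        aligned_b = ref[:36] + "-" + ref[37:]
        aln = AlignmentResult(ref, aligned_b, 149, 150, 0.0)
        assert map_positions(aln, scheme)[37] == (GAP, "-")

    def test_insertion_before_position_shifts_target_coordinate(self, scheme):
        ref = scheme.reference.sequence
        # one extra target residue inserted before reference position 37
        aligned_a = ref[:36] + "-" + ref[36:]
        aligned_b = ref[:36] + "W" + ref[36:]
        aln = AlignmentResult(aligned_a, aligned_b, 150, 151, 0.0)
        mapping = map_positions(aln, scheme)
        assert mapping[37] == (38, ref[36])

    def test_rejects_alignment_of_wrong_reference(self, scheme):
        aln = AlignmentResult("MK", "MK", 2, 2, 0.0)
        with pytest.raises(ValueError, match="not the scheme reference"):
            map_positions(aln, scheme)


class TestFindCxxc:
    @pytest.mark.parametrize(
        "seq,expected",
        [("ACDEC", [2]), ("WWAAGG", []), ("CAACAAC", [1, 4]), ("CCCC", [1])],
    )
    def test_examples(self, seq, expected):
        assert find_cxxc(ProteinRecord("x", seq)) == expected

    @given(st.text(alphabet="ACG", min_size=4, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_equals_brute_force_window_scan(self, seq):
        brute = [
            p + 1
            for p in range(len(seq))
            if p + 3 < len(seq) and seq[p] == "C" and seq[p + 3] == "C"
        ]
        assert find_cxxc(ProteinRecord("x", seq)) == brute


def _profile(res37, res85, res91, res93, res104, cys_count=4):
    residue_at = {p: (p, r) for p, r in
                  [(37, res37), (85, res85), (91, res91), (93, res93), (104, res104)]}
    for p in (96, 99, 136, 139):
        residue_at[p] = (p, "C" if cys_count == 4 else "A")
    return SiteProfile(residue_at=residue_at, cxxc_motifs=(96, 136), structural_cys_count=cys_count)


class TestClassifySubtype:
    @pytest.mark.parametrize(
        "residues,expected",
        [
            (("H", "D", "H", "H", "D"), Subtype.PERR_LIKE),
            # Glu replacing Asp85 with Asp retained at 104 stays PerR-like
            (("H", "E", "H", "H", "D"), Subtype.PERR_LIKE),
            (("H", "D", "H", "H", "E"), Subtype.FUR_LIKE),
            # S-donor Cys at 85 with the N-donor His37 absent
            (("A", "C", "H", "H", "D"), Subtype.ZUR_LIKE),
            (("A", "D", "H", "H", "D"), Subtype.UNCLASSIFIED),
            (("H", "D", "H", "H", "A"), Subtype.UNCLASSIFIED),
            (("X", "D", "H", "H", "D"), Subtype.UNCLASSIFIED),
        ],
    )
    def test_rule_cascade(self, residues, expected):
        call = classify_subtype(_profile(*residues))
        assert call.subtype is expected
        assert call.evidence  # every rule consulted is reported

    def test_his_at_37_blocks_zur_call(self):
        # Cys at 85 alone is not enough: His37 present keeps the His-triad path
        call = classify_subtype(_profile("H", "C", "H", "H", "D"))
        assert call.subtype is Subtype.PERR_LIKE

    def test_structural_site_flag_tracks_cys_count(self):
        assert classify_subtype(_profile("H", "D", "H", "H", "D")).has_structural_site
        assert not classify_subtype(
            _profile("H", "D", "H", "H", "D", cys_count=3)
        ).has_structural_site


class TestExtractSiteProfile:
    def test_reference_profile_is_the_perr_signature(self, scheme):
        profile = extract_site_profile(scheme.reference, scheme)
        residues = [profile.residue_at[p][1] for p in (37, 85, 91, 93, 104)]
        assert residues == ["H", "D", "H", "H", "D"]
        assert profile.structural_cys_count == 4
        assert set(profile.cxxc_motifs) >= {96, 136}

    def test_all_ala_sequence_has_no_structural_cys(self, scheme):
        profile = extract_site_profile(ProteinRecord("a", "A" * 150), scheme)
        assert profile.structural_cys_count == 0
        assert profile.cxxc_motifs == ()


class TestExtinctionCoefficient:
    @pytest.mark.parametrize(
        "seq,expected", [("AAGG", 0), ("WYY", 8480), ("W", 5500), ("Y", 1490)]
    )
    def test_trp_tyr_rule(self, seq, expected):
        assert extinction_coefficient_280(ProteinRecord("x", seq)) == expected

    @given(sequences, sequences)
    @settings(max_examples=50, deadline=None)
    def test_additive_under_concatenation(self, a, b):
        eps = extinction_coefficient_280
        assert eps(ProteinRecord("ab", a + b)) == eps(ProteinRecord("a", a)) + eps(
            ProteinRecord("b", b)
        )


class TestIdentityMatrix:
    def test_identical_pair_is_all_100(self):
        recs = [ProteinRecord("a", "MKWHDE"), ProteinRecord("b", "MKWHDE")]
        mat = identity_matrix(recs)
        assert (mat.to_numpy() == 100.0).all()

    def test_symmetric_with_100_diagonal(self):
        rng = np.random.default_rng(3)
        recs = [
            ProteinRecord(f"s{i}", "".join(rng.choice(list(AA20), 25)))
            for i in range(3)
        ]
        mat = identity_matrix(recs).to_numpy()
        assert np.allclose(mat, mat.T)
        assert np.allclose(np.diag(mat), 100.0)

    def test_duplicate_ids_rejected(self):
        recs = [ProteinRecord("a", "MKW"), ProteinRecord("a", "MKY")]
        with pytest.raises(SequenceError, match="duplicate"):
            identity_matrix(recs)


class TestReferenceScheme:
    def test_rejects_non_cys_structural_positions(self):
        with pytest.raises(ValueError, match="expected Cys"):
            ReferenceScheme(reference=ProteinRecord("r", "A" * 150))

    def test_rejects_positions_beyond_reference(self, scheme):
        with pytest.raises(ValueError, match="outside reference"):
            ReferenceScheme(
                reference=scheme.reference,
                structural_positions=(96, 99, 136, 139),
                regulatory_positions=(37, 85, 91, 93, 400),
            )
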