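"""Reporter locus validation, mismatch inference and coordinate conventions."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strandmmr.errors import ValidationError
from strandmmr.reporter import (
    ATT0_EDITS,
    COMPLEMENT,
    REPORTER_A_RUNS,
    MutationKind,
    MutationRecord,
    Orientation,
    Strand,
    StrandRole,
    apply_att0,
    build_reporter,
    default_locus,
    infer_mismatch,
    normalize_indel_position,
    synthetic_reporter_orf,
)

from .conftest import make_indel, make_substitution


class TestBuildReporter:
    def test_fixture_locus_is_valid_and_804_nt(self, locus_or1):
        assert len(locus_or1) == 804
        assert set(locus_or1.orf_sequence) <= set("ACGT")

    def test_orientation_flip_changes_leading_nascent(self):
        or1 = build_reporter("ACGT", "OR1")
        or2 = build_reporter("ACGT", "OR2")
        assert or1.leading_nascent != or2.leading_nascent

    @pytest.mark.parametrize(
        "sequence, orientation",
        [("ACGN", "OR1"), ("", "OR1"), ("ACGT", "OR3")],
    )
    def test_invalid_inputs_rejected(self, sequence, orientation):
        with pytest.raises(ValidationError):
            build_reporter(sequence, orientation)

    def test_fixture_embeds_documented_landmarks(self):
        seq = synthetic_reporter_orf()
        for lo, hi in REPORTER_A_RUNS:
            assert set(seq[lo - 1 : hi]) == {"A"}
            assert seq[lo - 2] != "A" and seq[hi] != "A"
        assert seq[278] == "A" and seq[685] == "A"
        assert seq[687:699] == "ATTATTATTGTT"


class TestInferMismatch:
    def test_hotspot_transversion_is_t_dt_on_leading_strand(self, locus_or1):
        """The signature case: A->T at 686 in OR1 made by the leading-strand
        replicase is a template T paired with a misinserted dT."""
        rec = make_substitution(locus_or1, 686, "T")
        mm = infer_mismatch(rec, locus_or1, StrandRole.LEADING)
        assert mm.notation == "T-dT"
        assert (mm.template_base, mm.nascent_base) == ("T", "T")

    def test_same_event_on_lagging_strand_is_the_complement(self, locus_or1):
        rec = make_substitution(locus_or1, 686, "T")
        assert infer_mismatch(rec, locus_or1, StrandRole.LAGGING).notation == "A-dA"

    def test_run_deletion_is_unpaired_template_t(self, locus_or1):
        """Deleting an A from a coding-strand A-run removes an A:T pair; the
        leading-strand nascent coding strand skips a template T."""
        rec = make_indel(locus_or1, 257, MutationKind.DELETION)
        mm = infer_mismatch(rec, locus_or1, StrandRole.LEADING)
        assert mm.indel_descriptor.base == "T"
        assert mm.indel_descriptor.strand == "template"

    def test_insertion_sits_on_nascent_strand(self, locus_or1):
        rec = make_indel(locus_or1, 257, MutationKind.INSERTION, base="A")
        mm = infer_mismatch(rec, locus_or1, StrandRole.LEADING)
        assert mm.indel_descriptor.strand == "nascent"
        assert mm.indel_descriptor.base == "A"

    def test_multibase_records_rejected(self, locus_or1):
        rec = MutationRecord("m1", 10, MutationKind.MULTIBASE)
        with pytest.raises(ValidationError):
            infer_mismatch(rec, locus_or1, StrandRole.LEADING)

    def test_position_out_of_range_rejected(self, locus_or1):
        rec = MutationRecord(
            "m1", 9000, MutationKind.SUBSTITUTION, ref_base="A", alt_base="T"
        )
        with pytest.raises(ValidationError):
            infer_mismatch(rec, locus_or1, StrandRole.LEADING)


def _all_substitution_cases():
    """All 12 substitution types, each at a fixture position carrying its ref."""
    seq = synthetic_reporter_orf()
    cases = []
    for ref in "ACGT":
        pos = seq.index(ref, 20) + 1
        for alt in "ACGT":
            if alt != ref:
                cases.append((pos, ref, alt))
    return cases


@pytest.mark.parametrize("orientation", [Orientation.OR1, Orientation.OR2])
@pytest.mark.parametrize("pos, ref, alt", _all_substitution_cases())
def test_leading_and_lagging_inferences_are_watson_crick_complements(
    orientation, pos, ref, alt
):
    locus = default_locus(orientation)
    rec = make_substitution(locus, pos, alt)
    leading = infer_mismatch(rec, locus, StrandRole.LEADING)
    lagging = infer_mismatch(rec, locus, StrandRole.LAGGING)
    # T-dT <-> A-dA, G-dT <-> C-dA, ...: both components complement
    assert leading.template_base == COMPLEMENT[lagging.template_base]
    assert leading.nascent_base == COMPLEMENT[lagging.nascent_base]


@pytest.mark.parametrize("pos, ref, alt", _all_substitution_cases())
def test_cross_orientation_equivalence(pos, ref, alt):
    """(OR1, leading) and (OR2, lagging) see the same nascent strand, so the
    same coding-strand change maps to the same mismatch — the rule that lets
    leading-strand errors in one orientation be compared with lagging-strand
    errors in the other."""
    or1, or2 = default_locus(Orientation.OR1), default_locus(Orientation.OR2)
    rec1 = make_substitution(or1, pos, alt)
    rec2 = make_substitution(or2, pos, alt)
    assert (
        infer_mismatch(rec1, or1, StrandRole.LEADING).notation
        == infer_mismatch(rec2, or2, StrandRole.LAGGING).notation
    )
    assert (
        infer_mismatch(rec1, or1, StrandRole.LAGGING).notation
        == infer_mismatch(rec2, or2, StrandRole.LEADING).notation
    )


class TestNormalizeIndelPosition:
    @pytest.mark.parametrize(
        "position, expected",
        [(177, 174), (174, 174), (203, 201), (258, 255), (260, 255)],
    )
    def test_run_indels_move_to_5prime_end(self, locus_or1, position, expected):
        rec = make_indel(locus_or1, position, MutationKind.DELETION)
        assert normalize_indel_position(rec, locus_or1).position == expected

    def test_isolated_indel_unchanged(self, locus_or1):
        # position 686 is an A flanked by non-A bases
        rec = make_indel(locus_or1, 686, MutationKind.DELETION)
        assert normalize_indel_position(rec, locus_or1).position == 686

    def test_substitution_passes_through(self, locus_or1):
        rec = make_substitution(locus_or1, 177, "T")
        assert normalize_indel_position(rec, locus_or1) is rec

    def test_matches_brute_force_run_scan_everywhere(self, locus_or1):
        """Independent oracle: linear scan for the run start at every ORF
        position, deleting the base actually present there."""
        seq = locus_or1.orf_sequence
        for pos in range(1, len(seq) + 1):
            base = seq[pos - 1]
            start = pos
            while start > 1 and seq[start - 2] == base:
                start -= 1
            rec = make_indel(locus_or1, pos, MutationKind.DELETION)
            normalized = normalize_indel_position(rec, locus_or1)
            assert normalized.position == start
            # idempotent and never 3'-ward
            assert normalize_indel_position(normalized, locus_or1).position == start
            assert normalized.position <= pos

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(position=st.integers(min_value=1, max_value=804),
           base=st.sampled_from("ACGT"),
           kind=st.sampled_from([MutationKind.DELETION, MutationKind.INSERTION]))
    def test_idempotent_and_5prime_monotone(self, locus_or1, position, base, kind):
        rec = make_indel(locus_or1, position, kind, base=base)
        once = normalize_indel_position(rec, locus_or1)
        twice = normalize_indel_position(once, locus_or1)
        assert once.position == twice.position <= position


class TestApplyAtt0:
    def test_edits_exactly_three_silent_positions(self, locus_or1):
        att0 = apply_att0(locus_or1)
        diffs = {
            i + 1
            for i, (a, b) in enumerate(
                zip(locus_or1.orf_sequence, att0.orf_sequence)
            )
            if a != b
        }
        assert diffs == set(ATT0_EDITS)
        assert att0.orf_sequence[687:699] == "ATAATCATAGTT"

    def test_second_application_fails(self, locus_or1):
        att0 = apply_att0(locus_or1)
        with pytest.raises(ValidationError):
            apply_att0(att0)

    def test_motif_absent_fails(self):
        locus = build_reporter("ACGT" * 200, "OR1")
        with pytest.raises(ValidationError):
            apply_att0(locus)


def test_default_strand_mapping_is_configurable():
    locus = build_reporter("ACGT", "OR1", leading_nascent=Strand.NONCODING)
    assert locus.leading_nascent is Strand.NONCODING
    rec = MutationRecord(
        "m1", 1, MutationKind.SUBSTITUTION, ref_base="A", alt_base="T"
    )
    # with the flipped mapping, OR1 leading behaves like default OR2 leading
    assert infer_mismatch(rec, locus, StrandRole.LEADING).notation == "A-dA"
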