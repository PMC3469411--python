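"""Reporter-locus model and nascent-strand mismatch inference.

A forward-mutation reporter (a *URA3*-style ORF integrated near a replication
origin) can be present in either of two orientations, OR1 and OR2. Flipping
the orientation swaps which physical ORF strand is synthesized as the nascent
leading strand, so a mutation observed on the coding strand corresponds to
different replication-error mismatches in the two orientations. Given a
mutator polymerase with a known strand role (leading for Pol epsilon mutators,
lagging for Pol alpha/delta mutators), each observed single-base mutation can
be converted into the mispair the polymerase actually made: a template base
paired with an incorrectly incorporated nascent deoxynucleotide, written
``X-dY`` (e.g. ``T-dT``), or a single unpaired base for indels.

Coordinates are 1-based positions on the coding strand throughout.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Optional

import numpy as np
from Bio import SeqIO

from .errors import ValidationError

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
VALID_BASES = frozenset("ACGT")

REPORTER_LENGTH = 804

#: 1-based start of the natural AT-rich triplet-repeat flank (ATT3) next to
#: the refractory hotspot at base pair 686.
ATT3_START = 688
ATT3_MOTIF = "ATTATTATTGTT"
#: Silent single-base edits that interrupt the triplet repeat (ATT3 -> ATT0).
ATT0_EDITS = {690: "A", 693: "C", 696: "A"}

#: Homonucleotide A-runs documented in the reporter (1-based, inclusive).
REPORTER_A_RUNS = ((174, 178), (201, 205), (255, 260))
#: A-T to T-A transversion hotspot positions for the leading-strand mutator.
HOTSPOT_POSITIONS = (279, 686)


class Orientation(str, enum.Enum):
    OR1 = "OR1"
    OR2 = "OR2"


class Strand(str, enum.Enum):
    CODING = "coding"
    NONCODING = "noncoding"

    @property
    def other(self) -> "Strand":
        return Strand.NONCODING if self is Strand.CODING else Strand.CODING


class StrandRole(str, enum.Enum):
    LEADING = "leading"
    LAGGING = "lagging"


class MmrStatus(str, enum.Enum):
    PROFICIENT = "proficient"
    DEFICIENT = "deficient"


class MutationKind(str, enum.Enum):
    SUBSTITUTION = "substitution"
    INSERTION = "insertion"
    DELETION = "deletion"
    MULTIBASE = "multibase"


#: Which ORF strand is the nascent leading strand, by orientation. OR1 is
#: pinned by the worked inference that an A->T change at bp 686 made by the
#: leading-strand replicase is a T-dT mismatch, which requires the nascent
#: leading strand to be the coding strand in OR1.
DEFAULT_LEADING_NASCENT = {
    Orientation.OR1: Strand.CODING,
    Orientation.OR2: Strand.NONCODING,
}


@dataclass(frozen=True)
class ReporterLocus:
    """A reporter ORF in a specific orientation.

    Parameters
    ----------
    orf_sequence
        Coding strand, 5'->3', A/C/G/T only.
    orientation
        OR1 or OR2.
    leading_nascent
        Which ORF strand is synthesized as the nascent leading strand in this
        orientation. Configurable because the physical layout relative to the
        origin is a property of the construct, not of the ORF.
    """

    orf_sequence: str
    orientation: Orientation
    leading_nascent: Strand
    locus_label: str = "AGP1::URA3"

    def __post_init__(self) -> None:
        if not self.orf_sequence:
            raise ValidationError("reporter ORF sequence is empty")
        bad = set(self.orf_sequence) - VALID_BASES
        if bad:
            raise ValidationError(
                f"reporter ORF contains non-ACGT characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.orf_sequence)

    def base(self, position: int) -> str:
        """Coding-strand base at a 1-based position."""
        if not 1 <= position <= len(self.orf_sequence):
            raise ValidationError(
                f"position {position} outside ORF of length {len(self.orf_sequence)}"
            )
        return self.orf_sequence[position - 1]

    def nascent_strand(self, strand_role: StrandRole) -> Strand:
        """Which ORF strand is nascent for a replicase with this strand role."""
        if strand_role is StrandRole.LEADING:
            return self.leading_nascent
        return self.leading_nascent.other


@dataclass(frozen=True)
class MutationRecord:
    """One sequenced mutant's change, in coding-strand ORF coordinates."""

    mutant_id: str
    position: int
    kind: MutationKind
    ref_base: Optional[str] = None
    alt_base: Optional[str] = None
    indel_base: Optional[str] = None
    strain: str = ""
    mmr_status: MmrStatus = MmrStatus.PROFICIENT
    orientation: Orientation = Orientation.OR1

    def validate(self, locus: ReporterLocus) -> None:
        if self.kind is MutationKind.MULTIBASE:
            return  # retained but never enters rate arithmetic
        if not 1 <= self.position <= len(locus):
            raise ValidationError(
                f"record {self.mutant_id}: position {self.position} outside "
                f"ORF of length {len(locus)}"
            )
        if self.kind is MutationKind.SUBSTITUTION:
            if self.ref_base not in VALID_BASES or self.alt_base not in VALID_BASES:
                raise ValidationError(
                    f"record {self.mutant_id}: substitution needs ref and alt bases"
                )
            actual = locus.base(self.position)
            if self.ref_base != actual:
                raise ValidationError(
                    f"record {self.mutant_id}: ref {self.ref_base} at position "
                    f"{self.position} does not match reporter base {actual}"
                )
        else:
            if self.indel_base not in VALID_BASES:
                raise ValidationError(
                    f"record {self.mutant_id}: single-base indel needs its base"
                )

    @property
    def is_single_base(self) -> bool:
        return self.kind is not MutationKind.MULTIBASE

    @property
    def is_transition(self) -> bool:
        if self.kind is not MutationKind.SUBSTITUTION:
            return False
        purines = {"A", "G"}
        return (self.ref_base in purines) == (self.alt_base in purines)

    @property
    def is_transversion(self) -> bool:
        return self.kind is MutationKind.SUBSTITUTION and not self.is_transition


@dataclass(frozen=True)
class UnpairedBase:
    """Indel intermediate: one base with no partner, on one strand."""

    base: str
    strand: str  # "template" or "nascent"


@dataclass(frozen=True)
class InferredMismatch:
    """The replication-error mispair behind an observed mutation.

    For substitutions ``notation`` is ``template_base + "-d" + nascent_base``
    (template base paired with the misincorporated nascent dNMP). Indels carry
    an :class:`UnpairedBase` descriptor instead.
    """

    strand_role: StrandRole
    template_base: Optional[str] = None
    nascent_base: Optional[str] = None
    notation: str = ""
    indel_descriptor: Optional[UnpairedBase] = None


def build_reporter(
    orf_sequence: str,
    orientation: Orientation | str,
    leading_nascent: Strand | str | None = None,
    locus_label: str = "AGP1::URA3",
) -> ReporterLocus:
    """Construct and validate a :class:`ReporterLocus`.

    ``leading_nascent`` defaults to the standard construct layout
    (OR1 -> coding strand nascent leading, OR2 -> noncoding).
    """
    try:
        orientation = Orientation(orientation)
    except ValueError as exc:
        raise ValidationError(f"invalid orientation {orientation!r}") from exc
    if leading_nascent is None:
        leading_nascent = DEFAULT_LEADING_NASCENT[orientation]
    else:
        try:
            leading_nascent = Strand(leading_nascent)
        except ValueError as exc:
            raise ValidationError(
                f"invalid strand label {leading_nascent!r}"
            ) from exc
    return ReporterLocus(
        orf_sequence=str(orf_sequence).upper(),
        orientation=orientation,
        leading_nascent=leading_nascent,
        locus_label=locus_label,
    )


def infer_mismatch(
    record: MutationRecord,
    locus: ReporterLocus,
    strand_role: StrandRole | str,
) -> InferredMismatch:
    """Convert an observed coding-strand mutation into the nascent-strand
    mispair made by a replicase with the given strand role.

    The nascent strand for (orientation, strand role) is looked up on the
    locus. A substitution observed as ref->alt on the coding strand is, if the
    nascent strand IS the coding strand, a misincorporation of ``alt``
    opposite the noncoding-strand template base (the complement of ``ref``);
    if the nascent strand is the noncoding strand, it is the complement of
    ``alt`` opposite ``ref``. Deletions leave the skipped base unpaired on the
    template strand; insertions leave the extra base unpaired on the nascent
    strand.
    """
    strand_role = StrandRole(strand_role)
    if record.kind is MutationKind.MULTIBASE:
        raise ValidationError(
            f"record {record.mutant_id}: multi-base records have no single "
            "inferred mismatch"
        )
    record.validate(locus)
    nascent = locus.nascent_strand(strand_role)

    if record.kind is MutationKind.SUBSTITUTION:
        if nascent is Strand.CODING:
            template_base = COMPLEMENT[record.ref_base]
            nascent_base = record.alt_base
        else:
            template_base = record.ref_base
            nascent_base = COMPLEMENT[record.alt_base]
        return InferredMismatch(
            strand_role=strand_role,
            template_base=template_base,
            nascent_base=nascent_base,
            notation=f"{template_base}-d{nascent_base}",
        )

    if record.kind is MutationKind.DELETION:
        # the template strand (opposite the nascent strand) retains the base
        template = nascent.other
        base = (
            record.indel_base
            if template is Strand.CODING
            else COMPLEMENT[record.indel_base]
        )
        descriptor = UnpairedBase(base=base, strand="template")
    else:  # insertion: extra base sits on the nascent strand
        base = (
            record.indel_base
            if nascent is Strand.CODING
            else COMPLEMENT[record.indel_base]
        )
        descriptor = UnpairedBase(base=base, strand="nascent")
    return InferredMismatch(
        strand_role=strand_role,
        notation=f"unpaired {descriptor.base} ({descriptor.strand})",
        indel_descriptor=descriptor,
    )


def normalize_indel_position(
    record: MutationRecord, locus: ReporterLocus
) -> MutationRecord:
    """Rewrite an indel's position to the 5'-most coordinate of the coding
    strand homonucleotide run it falls in; substitutions pass through.

    Single-base indels inside a run are positionally ambiguous, so spectra
    conventionally place them at the run's 5' end. Idempotent, and never moves
    a record 3'-ward.
    """
    if record.kind not in (MutationKind.INSERTION, MutationKind.DELETION):
        return record
    record.validate(locus)
    seq = locus.orf_sequence
    i = record.position - 1
    if seq[i] != record.indel_base:
        return record  # not inside a run of its own base
    while i > 0 and seq[i - 1] == record.indel_base:
        i -= 1
    if i + 1 == record.position:
        return record
    return replace(record, position=i + 1)


def apply_att0(locus: ReporterLocus) -> ReporterLocus:
    """Interrupt the ATT triplet repeat flanking base pair 686.

    Applies the three silent edits (690 T->A, 693 T->C, 696 T->A) that
    convert the natural 5'-ATT ATT ATT GTT flank (ATT3) into
    5'-ATA ATC ATA GTT (ATT0). Raises if the ATT3 motif is not present at
    the expected coordinates, so applying it twice is an error.
    """
    start, end = ATT3_START, ATT3_START + len(ATT3_MOTIF)
    if len(locus) < end - 1:
        raise ValidationError("reporter too short to carry the ATT3 motif")
    window = locus.orf_sequence[start - 1 : end - 1]
    if window != ATT3_MOTIF:
        raise ValidationError(
            f"ATT3 motif {ATT3_MOTIF} not found at positions {start}-{end - 1} "
            f"(saw {window}); already converted to ATT0?"
        )
    seq = list(locus.orf_sequence)
    for pos, base in ATT0_EDITS.items():
        seq[pos - 1] = base
    return replace(locus, orf_sequence="".join(seq))


@lru_cache(maxsize=1)
def synthetic_reporter_orf() -> str:
    """Deterministic 804-nt synthetic reporter ORF used as the test fixture.

    The true reporter sequence is not bundled; this synthetic stand-in embeds
    the documented landmarks — homonucleotide A-runs at 174-178, 201-205 and
    255-260, the ATT3 triplet-repeat flank at 688-699, and A:T pairs at the
    transversion hotspot positions 279 and 686 — in an otherwise random
    background with no other homonucleotide run longer than three bases. Any
    user-supplied FASTA is accepted in its place.
    """
    rng = np.random.default_rng(20121011)
    seq = list(rng.choice(list("ACGT"), size=REPORTER_LENGTH))

    pinned: dict[int, str] = {}  # 0-based index -> base

    def pin(pos1: int, base: str) -> None:
        pinned[pos1 - 1] = base

    for b, pos1 in zip("ATG", (1, 2, 3)):
        pin(pos1, b)
    for b, pos1 in zip("TAA", (802, 803, 804)):
        pin(pos1, b)
    for lo, hi in REPORTER_A_RUNS:
        for pos1 in range(lo, hi + 1):
            pin(pos1, "A")
        pin(lo - 1, "C")  # run boundaries must break the run
        pin(hi + 1, "G")
    for pos1 in HOTSPOT_POSITIONS:
        pin(pos1, "A")
        pin(pos1 - 1, "C")
        pin(pos1 + 1, "G")
    for offset, b in enumerate(ATT3_MOTIF):
        pin(ATT3_START + offset, b)
    pin(ATT3_START - 1, "G")  # isolate the hotspot/motif from the background
    pin(ATT3_START + len(ATT3_MOTIF), "C")

    for idx, base in pinned.items():
        seq[idx] = base

    # break any accidental homonucleotide run of length >= 4 outside the
    # pinned landmarks, deterministically
    changed = True
    while changed:
        changed = False
        i = 0
        while i < REPORTER_LENGTH:
            j = i
            while j + 1 < REPORTER_LENGTH and seq[j + 1] == seq[i]:
                j += 1
            if j - i + 1 >= 4:
                for k in range(i, j + 1):
                    if k not in pinned:
                        left = seq[k - 1] if k > 0 else ""
                        right = seq[k + 1] if k + 1 < REPORTER_LENGTH else ""
                        seq[k] = next(
                            b for b in "CGTA" if b not in (seq[k], left, right)
                        )
                        changed = True
                        break
            i = j + 1
    return "".join(seq)


def default_locus(
    orientation: Orientation | str = Orientation.OR1,
    att_variant: str = "ATT3",
) -> ReporterLocus:
    """The synthetic fixture locus, optionally with the ATT0 flank."""
    locus = build_reporter(synthetic_reporter_orf(), orientation)
    if att_variant == "ATT0":
        locus = apply_att0(locus)
    elif att_variant != "ATT3":
        raise ValidationError(f"unknown ATT variant {att_variant!r}")
    return locus


def read_reporter_fasta(path) -> str:
    """Read a single-record FASTA holding the reporter coding strand."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValidationError(
            f"{path}: expected exactly one FASTA record, found {len(records)}"
        )
    return str(records[0].seq).upper()


def write_reporter_fasta(sequence: str, path, label: str = "reporter") -> None:
    with open(path, "w") as fh:
        fh.write(f">{label}\n")
        for i in range(0, len(sequence), 60):
            fh.write(sequence[i : i + 60] + "\n")
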