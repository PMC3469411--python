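"""Infer the nascent-strand mismatch behind an observed mutation.

The same coding-strand change corresponds to different replication-error
mispairs depending on the reporter orientation and on which strand the
mutator polymerase synthesizes. The signature case: an A->T transversion at
base pair 686 in orientation 1, made by a leading-strand (Pol epsilon-like)
mutator, is a template T paired with a misinserted dT (written T-dT).
"""

from strandmmr import (
    MutationKind,
    MutationRecord,
    Orientation,
    default_locus,
    infer_mismatch,
    normalize_indel_position,
)

for orientation in (Orientation.OR1, Orientation.OR2):
    locus = default_locus(orientation)
    record = MutationRecord(
        mutant_id="example",
        position=686,
        kind=MutationKind.SUBSTITUTION,
        ref_base="A",
        alt_base="T",
        orientation=orientation,
    )
    for role in ("leading", "lagging"):
        mm = infer_mismatch(record, locus, role)
        print(f"A->T at 686, {orientation.value}, {role:7s} -> {mm.notation}")

# a deletion inside the A-run at 255-260 is an unpaired base; spectra place
# run indels at the run's 5'-most position
locus = default_locus(Orientation.OR1)
deletion = MutationRecord(
    mutant_id="example",
    position=258,
    kind=MutationKind.DELETION,
    indel_base="A",
)
normalized = normalize_indel_position(deletion, locus)
mm = infer_mismatch(normalized, locus, "leading")
print(f"\ndel A at 258 -> normalized to position {normalized.position}, "
      f"inferred as {mm.notation}")
print(
    "\nLeading and lagging assignments of the same event are Watson-Crick"
    "\ncomplements; OR1/leading matches OR2/lagging, which is why factors"
    "\nfor the same mismatch are compared across opposite orientations."
)
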