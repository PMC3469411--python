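import pytest

from strandmmr.reporter import (
    MmrStatus,
    MutationKind,
    MutationRecord,
    Orientation,
    default_locus,
)
from strandmmr.spectra import Spectrum


@pytest.fixture(scope="session")
def locus_or1():
    return default_locus(Orientation.OR1)


@pytest.fixture(scope="session")
def locus_or2():
    return default_locus(Orientation.OR2)


@pytest.fixture(scope="session")
def locus_att0():
    return default_locus(Orientation.OR1, att_variant="ATT0")


def make_substitution(
    locus,
    position,
    alt,
    mutant_id="m1",
    strain="s",
    mmr_status=MmrStatus.PROFICIENT,
):
    """Substitution record whose ref is read off the locus."""
    return MutationRecord(
        mutant_id=mutant_id,
        position=position,
        kind=MutationKind.SUBSTITUTION,
        ref_base=locus.base(position),
        alt_base=alt,
        strain=strain,
        mmr_status=mmr_status,
        orientation=locus.orientation,
    )


def make_indel(locus, position, kind, base=None, mutant_id="m1", strain="s",
               mmr_status=MmrStatus.PROFICIENT):
    return MutationRecord(
        mutant_id=mutant_id,
        position=position,
        kind=kind,
        indel_base=base if base is not None else locus.base(position),
        strain=strain,
        mmr_status=mmr_status,
        orientation=locus.orientation,
    )


def make_spectrum(records, n_sequenced=None, n_no_orf_change=0, strain="s",
                  mmr_status=MmrStatus.PROFICIENT,
                  orientation=Orientation.OR1):
    return Spectrum(
        records=tuple(records),
        n_sequenced=n_sequenced if n_sequenced is not None else len(records),
        n_no_orf_change=n_no_orf_change,
        strain=strain,
        mmr_status=mmr_status,
        orientation=orientation,
    )
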