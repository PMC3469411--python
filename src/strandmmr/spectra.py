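"""Mutational spectra: containers, TSV IO, class counting, rate partitioning
and hotspot detection.

A spectrum is the collection of independent sequenced mutants from one strain
(genotype, MMR status, reporter orientation), together with the total number
sequenced and the number that showed no change in the reporter ORF. The
overall mutation rate from the fluctuation assay is partitioned into
per-class or per-site rates in proportion to spectrum counts; those class
rates are the inputs to the MMR correction-factor arithmetic.

Multi-base mutations are retained in the container but never enter any count
or rate: only single-base substitutions and single-base indels are scored.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .reporter import (
    MmrStatus,
    MutationKind,
    MutationRecord,
    Orientation,
    ReporterLocus,
    StrandRole,
    infer_mismatch,
    normalize_indel_position,
)

SPECTRUM_COLUMNS = [
    "mutant_id",
    "strain",
    "mmr_status",
    "orientation",
    "position",
    "kind",
    "ref",
    "alt",
]


@dataclass(frozen=True)
class Spectrum:
    """Sequenced-mutant records for one strain, with sequencing totals.

    ``n_sequenced`` counts every independent 5-FOA-resistant mutant whose
    reporter was sequenced, including those with no ORF change; it is the
    default denominator when partitioning the overall rate.
    """

    records: tuple[MutationRecord, ...]
    n_sequenced: int
    n_no_orf_change: int = 0
    strain: str = ""
    mmr_status: MmrStatus = MmrStatus.PROFICIENT
    orientation: Orientation = Orientation.OR1

    def __post_init__(self) -> None:
        if self.n_sequenced < 0 or self.n_no_orf_change < 0:
            raise ValidationError("sequencing totals must be non-negative")
        if self.n_sequenced < self.n_no_orf_change:
            raise ValidationError("n_sequenced must be >= n_no_orf_change")
        for rec in self.records:
            if rec.mmr_status != self.mmr_status or rec.orientation != self.orientation:
                raise ValidationError(
                    f"record {rec.mutant_id} labels do not match the spectrum "
                    f"({self.strain}, {self.mmr_status.value}, {self.orientation.value})"
                )
        object.__setattr__(self, "records", tuple(self.records))

    @property
    def n_multibase(self) -> int:
        return sum(r.kind is MutationKind.MULTIBASE for r in self.records)

    def normalized(self, locus: ReporterLocus) -> "Spectrum":
        """Copy with all indels moved to their run's 5'-most position."""
        recs = tuple(
            normalize_indel_position(r, locus) if r.is_single_base else r
            for r in self.records
        )
        return replace(self, records=recs)


# ---------------------------------------------------------------------------
# class selectors


@dataclass(frozen=True)
class ClassSelector:
    """A named pure predicate over (record, locus) defining a mutation class."""

    name: str
    predicate: Callable[[MutationRecord, ReporterLocus], bool]

    def __call__(self, record: MutationRecord, locus: ReporterLocus) -> bool:
        if record.kind is MutationKind.MULTIBASE:
            return False
        return self.predicate(record, locus)


def all_single_base() -> ClassSelector:
    return ClassSelector("all_single_base", lambda r, loc: True)


def transitions() -> ClassSelector:
    return ClassSelector("transition", lambda r, loc: r.is_transition)


def transversions() -> ClassSelector:
    return ClassSelector("transversion", lambda r, loc: r.is_transversion)


def substitutions() -> ClassSelector:
    return ClassSelector(
        "substitution", lambda r, loc: r.kind is MutationKind.SUBSTITUTION
    )


def single_insertions() -> ClassSelector:
    return ClassSelector(
        "single_insertion", lambda r, loc: r.kind is MutationKind.INSERTION
    )


def single_deletions() -> ClassSelector:
    return ClassSelector(
        "single_deletion", lambda r, loc: r.kind is MutationKind.DELETION
    )


def specific_change(ref: str, alt: str) -> ClassSelector:
    return ClassSelector(
        f"change_{ref}>{alt}",
        lambda r, loc: r.kind is MutationKind.SUBSTITUTION
        and r.ref_base == ref
        and r.alt_base == alt,
    )


def site(position: int) -> ClassSelector:
    return ClassSelector(f"site_{position}", lambda r, loc: r.position == position)


def site_and_change(position: int, ref: str, alt: str) -> ClassSelector:
    inner = specific_change(ref, alt)
    return ClassSelector(
        f"site_{position}_{ref}>{alt}",
        lambda r, loc: r.position == position and inner(r, loc),
    )


def inferred_mismatch_class(notation: str, strand_role: StrandRole | str) -> ClassSelector:
    """Select records whose inferred mismatch has the given ``X-dY`` notation
    (or unpaired-base notation) under the given replicase strand role."""
    strand_role = StrandRole(strand_role)

    def pred(r: MutationRecord, loc: ReporterLocus) -> bool:
        return infer_mismatch(r, loc, strand_role).notation == notation

    return ClassSelector(f"mismatch_{notation}_{strand_role.value}", pred)


STANDARD_CLASSES: tuple[str, ...] = (
    "all_single_base",
    "substitution",
    "transition",
    "transversion",
    "single_insertion",
    "single_deletion",
)


def standard_selectors() -> list[ClassSelector]:
    """The class selectors reported by default in pipeline summaries."""
    return [
        all_single_base(),
        substitutions(),
        transitions(),
        transversions(),
        single_insertions(),
        single_deletions(),
    ]


# ---------------------------------------------------------------------------
# IO


def write_spectrum(spectrum: Spectrum, path) -> None:
    """Write a spectrum as TSV with ``# key=value`` metadata header lines."""
    rows = []
    for r in spectrum.records:
        if r.kind is MutationKind.SUBSTITUTION:
            ref, alt = r.ref_base, r.alt_base
        elif r.kind is MutationKind.DELETION:
            ref, alt = r.indel_base, "-"
        elif r.kind is MutationKind.INSERTION:
            ref, alt = "-", r.indel_base
        else:
            ref, alt = r.ref_base or ".", r.alt_base or "."
        rows.append(
            dict(
                mutant_id=r.mutant_id,
                strain=r.strain,
                mmr_status=r.mmr_status.value,
                orientation=r.orientation.value,
                position=r.position,
                kind=r.kind.value,
                ref=ref,
                alt=alt,
            )
        )
    with open(path, "w") as fh:
        fh.write(f"# strain={spectrum.strain}\n")
        fh.write(f"# mmr_status={spectrum.mmr_status.value}\n")
        fh.write(f"# orientation={spectrum.orientation.value}\n")
        fh.write(f"# n_sequenced={spectrum.n_sequenced}\n")
        fh.write(f"# n_no_orf_change={spectrum.n_no_orf_change}\n")
        pd.DataFrame(rows, columns=SPECTRUM_COLUMNS).to_csv(
            fh, sep="\t", index=False
        )


def read_spectrum(path, locus: Optional[ReporterLocus] = None) -> Spectrum:
    """Read a spectrum TSV; validates each row (against ``locus`` if given),
    reporting the offending line number on failure."""
    meta: dict[str, str] = {}
    header_lines = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
    df = pd.read_csv(path, sep="\t", skiprows=header_lines, dtype=str)
    missing = set(SPECTRUM_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")

    records: list[MutationRecord] = []
    for idx, row in df.iterrows():
        lineno = header_lines + idx + 2  # 1-based, after the column header
        try:
            kind = MutationKind(row["kind"])
            position = int(row["position"])
            ref = None if pd.isna(row["ref"]) or row["ref"] in ("-", ".") else row["ref"]
            alt = None if pd.isna(row["alt"]) or row["alt"] in ("-", ".") else row["alt"]
            if kind is MutationKind.SUBSTITUTION:
                rec = MutationRecord(
                    mutant_id=row["mutant_id"],
                    position=position,
                    kind=kind,
                    ref_base=ref,
                    alt_base=alt,
                    strain=row["strain"],
                    mmr_status=MmrStatus(row["mmr_status"]),
                    orientation=Orientation(row["orientation"]),
                )
            elif kind in (MutationKind.DELETION, MutationKind.INSERTION):
                rec = MutationRecord(
                    mutant_id=row["mutant_id"],
                    position=position,
                    kind=kind,
                    indel_base=ref if kind is MutationKind.DELETION else alt,
                    strain=row["strain"],
                    mmr_status=MmrStatus(row["mmr_status"]),
                    orientation=Orientation(row["orientation"]),
                )
            else:
                rec = MutationRecord(
                    mutant_id=row["mutant_id"],
                    position=position,
                    kind=kind,
                    ref_base=ref,
                    alt_base=alt,
                    strain=row["strain"],
                    mmr_status=MmrStatus(row["mmr_status"]),
                    orientation=Orientation(row["orientation"]),
                )
            if locus is not None:
                rec.validate(locus)
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path}: line {lineno}: {exc}") from exc
        records.append(rec)

    return Spectrum(
        records=tuple(records),
        n_sequenced=int(meta.get("n_sequenced", len(records))),
        n_no_orf_change=int(meta.get("n_no_orf_change", 0)),
        strain=meta.get("strain", ""),
        mmr_status=MmrStatus(meta.get("mmr_status", "proficient")),
        orientation=Orientation(meta.get("orientation", "OR1")),
    )


# ---------------------------------------------------------------------------
# counting and rate partitioning


def count_class(
    spectrum: Spectrum, selector: ClassSelector, locus: ReporterLocus
) -> int:
    """Number of records in the class, after indel run-normalization.

    Multi-base records never count.
    """
    norm = spectrum.normalized(locus)
    return sum(bool(selector(r, locus)) for r in norm.records)


@dataclass(frozen=True)
class ClassRate:
    """A per-class mutation rate: the overall rate split by spectrum share."""

    rate: float
    count: int
    denominator: int
    total_rate: float
    selector_name: str
    zero_count: bool = False

    @property
    def unit_rate(self) -> float:
        """Rate contributed by a single observation (the pseudocount scale)."""
        return self.total_rate / self.denominator


def partition_rate(
    total_rate,
    spectrum: Spectrum,
    selector: ClassSelector,
    locus: ReporterLocus,
    include_no_orf_change: bool = True,
) -> ClassRate:
    """Class rate = overall rate x (class count / sequenced denominator).

    By default the denominator is all sequenced mutants including those with
    no ORF change (they were genuine resistant isolates);
    ``include_no_orf_change=False`` restricts it to mutants with an ORF
    change.
    """
    rate_value = getattr(total_rate, "rate", total_rate)
    denom = spectrum.n_sequenced
    if not include_no_orf_change:
        denom -= spectrum.n_no_orf_change
    if denom <= 0:
        raise ValidationError("spectrum has no sequenced mutants to partition over")
    count = count_class(spectrum, selector, locus)
    return ClassRate(
        rate=rate_value * count / denom,
        count=count,
        denominator=denom,
        total_rate=rate_value,
        selector_name=selector.name,
        zero_count=(count == 0),
    )


# ---------------------------------------------------------------------------
# hotspots


def hotspot_scan(
    spectrum: Spectrum,
    locus: ReporterLocus,
    alpha: float = 0.05,
) -> list[tuple[int, int, float]]:
    """Scan for positions carrying significantly more mutations than a
    uniform spread over the reporter would produce.

    Each mutated position's count is tested against Binomial(n, 1/L) where
    ``n`` is the number of single-base records and ``L`` the reporter length;
    upper-tail p-values are Bonferroni-adjusted across the L positions.
    Returns ``(position, count, adjusted p)`` for sites with adjusted
    p <= alpha, sorted by decreasing count. The test is deliberately simple
    and conservative; it flags strong enrichment, not subtle clustering.
    """
    norm = spectrum.normalized(locus)
    single = [r for r in norm.records if r.is_single_base]
    if not single:
        return []
    n = len(single)
    length = len(locus)
    positions, counts = np.unique([r.position for r in single], return_counts=True)
    pvals = stats.binom.sf(counts - 1, n, 1.0 / length)
    adjusted = np.minimum(pvals * length, 1.0)
    hits = [
        (int(p), int(c), float(a))
        for p, c, a in zip(positions, counts, adjusted)
        if a <= alpha
    ]
    hits.sort(key=lambda t: (-t[1], t[0]))
    return hits
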