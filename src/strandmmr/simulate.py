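"""Synthetic in-silico studies with the statistical structure the analysis
assumes, plus truth tables for parameter recovery.

The generator emulates a paired-strain reporter study: for each mutator
polymerase background, an MMR-proficient strain and its msh2-null partner
carry the reporter in one of two orientations, fluctuation assays yield
Luria-Delbruck-distributed mutant counts per culture, and a sample of
resistant mutants is sequenced to give a mutational spectrum. Per-site error
rates (the msh2-null, i.e. unrepaired, rates) and per-site repair
efficiencies fully determine both the overall 5-FOA-resistance rate of each
strain and the multinomial site/change probabilities of its spectrum, so
every quantity the pipeline estimates has a known true value recorded in the
truth table.

Structure emulated by the defaults:

* a leading-strand mutator ("pol2-M644G"-like) whose signature substitution
  is a nascent dT opposite template T, observed as A->T transversions on the
  coding strand in orientation 1;
* transversion hotspots at positions 279 and 686 (20x the background A->T
  rate), present in orientation 1 only;
* single-base indels concentrated in the reporter's homonucleotide A-runs;
* one repair-refractory site: the A->T change at position 686 has repair
  efficiency 0 while the natural ATT triplet-repeat flank (ATT3) is present,
  and its intrinsic efficiency (correction factor 35) once the flank is
  interrupted (ATT0);
* class-average repair efficiencies giving correction factors of roughly
  1500 (deletions), 1100 (insertions), 440 (transitions) and 72
  (transversions), and a small fraction of resistant mutants with no change
  in the ORF.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import ValidationError
from .fluctuation import FluctuationExperiment, simulate_cultures
from .reporter import (
    HOTSPOT_POSITIONS,
    REPORTER_A_RUNS,
    MmrStatus,
    MutationKind,
    MutationRecord,
    Orientation,
    ReporterLocus,
    StrandRole,
    default_locus,
    write_reporter_fasta,
)
from .spectra import Spectrum, write_spectrum

__all__ = [
    "SiteError",
    "ErrorModel",
    "StrainSpec",
    "StudyDesign",
    "StudyDataset",
    "default_model_config",
    "build_error_model",
    "default_design",
    "simulate_study",
]

TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
TRANSVERSION_PARTNER = {"A": "T", "T": "A", "G": "T", "C": "A"}

BOTH_ORIENTATIONS = (Orientation.OR1, Orientation.OR2)


@dataclass(frozen=True)
class SiteError:
    """One (position, change) error channel of the mutator polymerase.

    ``rate`` is the error rate with MMR absent (the msh2-null rate, per
    replication of the reporter); ``efficiency`` is the intrinsic fraction of
    these mismatches MMR removes in a proficient strain, before any
    context-dependent suppression (refractory sites) is applied.
    ``change`` is ``"R>A"`` for substitutions, ``"del:B"`` / ``"ins:B"`` for
    single-base indels of base B, all in coding-strand terms.
    """

    position: int
    change: str
    rate: float
    efficiency: float
    orientations: tuple[Orientation, ...] = BOTH_ORIENTATIONS

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValidationError("site error rates must be >= 0")
        if not 0 <= self.efficiency <= 1:
            raise ValidationError("repair efficiencies must be in [0, 1]")

    @property
    def kind(self) -> MutationKind:
        if ">" in self.change:
            return MutationKind.SUBSTITUTION
        if self.change.startswith("del:"):
            return MutationKind.DELETION
        if self.change.startswith("ins:"):
            return MutationKind.INSERTION
        raise ValidationError(f"unparseable change {self.change!r}")

    def to_record(
        self,
        mutant_id: str,
        strain: str,
        mmr_status: MmrStatus,
        orientation: Orientation,
    ) -> MutationRecord:
        kind = self.kind
        if kind is MutationKind.SUBSTITUTION:
            ref, alt = self.change.split(">")
            return MutationRecord(
                mutant_id=mutant_id,
                position=self.position,
                kind=kind,
                ref_base=ref,
                alt_base=alt,
                strain=strain,
                mmr_status=mmr_status,
                orientation=orientation,
            )
        return MutationRecord(
            mutant_id=mutant_id,
            position=self.position,
            kind=kind,
            indel_base=self.change.split(":")[1],
            strain=strain,
            mmr_status=mmr_status,
            orientation=orientation,
        )


def classify_change(site: SiteError) -> str:
    """Standard class name for a site-error channel."""
    kind = site.kind
    if kind is MutationKind.DELETION:
        return "single_deletion"
    if kind is MutationKind.INSERTION:
        return "single_insertion"
    ref, alt = site.change.split(">")
    purines = {"A", "G"}
    return "transition" if (ref in purines) == (alt in purines) else "transversion"


@dataclass(frozen=True)
class ErrorModel:
    """Per-site error rates and repair efficiencies for one mutator."""

    mutator: str
    strand_role: StrandRole
    sites: tuple[SiteError, ...]
    refractory_sites: frozenset[tuple[int, str]] = frozenset()
    no_orf_change_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.no_orf_change_fraction < 1:
            raise ValidationError("no_orf_change_fraction must be in [0, 1)")

    def efficiency_of(self, site: SiteError, att_variant: str) -> float:
        """Effective repair efficiency; refractory sites are 0 under ATT3."""
        if att_variant == "ATT3" and (site.position, site.change) in self.refractory_sites:
            return 0.0
        return site.efficiency

    def sites_for(
        self,
        orientation: Orientation,
        mmr_status: MmrStatus,
        att_variant: str = "ATT3",
    ) -> list[tuple[SiteError, float]]:
        """Active (site, effective rate) pairs for a strain configuration."""
        out = []
        for s in self.sites:
            if orientation not in s.orientations:
                continue
            rate = s.rate
            if mmr_status is MmrStatus.PROFICIENT:
                rate *= 1.0 - self.efficiency_of(s, att_variant)
            out.append((s, rate))
        return out

    def total_rate(
        self,
        orientation: Orientation,
        mmr_status: MmrStatus,
        att_variant: str = "ATT3",
    ) -> float:
        """Total 5-FOA-resistance rate per cell division for this strain.

        The reporter-inactivating channel is the sum of site rates; mutants
        with no ORF change make up ``no_orf_change_fraction`` of resistant
        isolates, so the total rate is inflated accordingly.
        """
        orf = sum(r for _, r in self.sites_for(orientation, mmr_status, att_variant))
        return orf / (1.0 - self.no_orf_change_fraction)

    def expected_class_cfs(self, att_variant: str = "ATT3") -> dict[str, dict[str, float]]:
        """True per-class correction factors implied by the model.

        Returns ``{class: {"OR1": cf, "OR2": cf, "combined": geometric mean}}``
        (orientations without observations of the class are omitted).
        """
        out: dict[str, dict[str, float]] = {}
        for orientation in BOTH_ORIENTATIONS:
            num: dict[str, float] = {}
            den: dict[str, float] = {}
            for s, _ in self.sites_for(orientation, MmrStatus.DEFICIENT, att_variant):
                cls = classify_change(s)
                eff = self.efficiency_of(s, att_variant)
                for key in (cls, "all_single_base", "substitution" if s.kind is MutationKind.SUBSTITUTION else None):
                    if key is None:
                        continue
                    num[key] = num.get(key, 0.0) + s.rate
                    den[key] = den.get(key, 0.0) + s.rate * (1.0 - eff)
            for cls, total in num.items():
                if den[cls] > 0:
                    out.setdefault(cls, {})[orientation.value] = total / den[cls]
        for cls, per in out.items():
            values = [v for k, v in per.items() if k in ("OR1", "OR2")]
            per["combined"] = float(np.exp(np.mean(np.log(values))))
        return out

    def expected_site_cf(
        self, position: int, orientation: Orientation, att_variant: str = "ATT3"
    ) -> Optional[float]:
        """True correction factor for all changes at one position."""
        num = den = 0.0
        for s, _ in self.sites_for(orientation, MmrStatus.DEFICIENT, att_variant):
            if s.position != position:
                continue
            num += s.rate
            den += s.rate * (1.0 - self.efficiency_of(s, att_variant))
        if num == 0 or den == 0:
            return None
        return num / den


def default_model_config() -> dict:
    """Study-condition defaults for the synthetic leading-strand-mutator model.

    Class rates are msh2-null totals per replication; dividing by the
    efficiency complements gives a proficient all-single-base rate around
    7e-8 against a deficient rate around 1.5e-5, i.e. an overall correction
    factor in the few-hundreds, matching the regime of a strong mutator
    background. Class efficiencies encode correction factors of 1500
    (deletions), 1100 (insertions), 440 (transitions) and 72 (transversions);
    the leading-strand A->T signature sites get correction factor 41, and the
    refractory site at 686 correction factor 35 once the ATT3 flank is
    interrupted.
    """
    return {
        "mutator": "pol2-M644G",
        "strand_role": "leading",
        "class_rates": {
            "transition": 8.0e-6,
            "transversion": 2.9e-6,
            "single_deletion": 2.2e-6,
            "single_insertion": 1.45e-6,
        },
        "class_efficiencies": {
            "transition": 1 - 1 / 440.0,
            "transversion": 1 - 1 / 72.0,
            "single_deletion": 1 - 1 / 1500.0,
            "single_insertion": 1 - 1 / 1100.0,
        },
        "n_substitution_sites": 150,
        "signature_change": "A>T",  # nascent dT opposite template T in OR1
        "signature_efficiency": 1 - 1 / 41.0,
        # the signature class is elevated in the orientation where the
        # mutator's nascent strand is the coding strand
        "signature_or1_multiplier": 4.0,
        "hotspots": [
            {"position": 279, "change": "A>T", "multiplier": 8.0,
             "orientations": ["OR1"], "efficiency": 1 - 1 / 41.0},
            {"position": 686, "change": "A>T", "multiplier": 8.0,
             "orientations": ["OR1"], "efficiency": 1 - 1 / 35.0},
        ],
        "refractory_sites": [{"position": 686, "change": "A>T"}],
        "no_orf_change_fraction": 0.05,
    }


def build_error_model(
    config: Optional[dict] = None, locus: Optional[ReporterLocus] = None
) -> ErrorModel:
    """Build a fully specified :class:`ErrorModel` from a configuration.

    Substitution channels are spread over ``n_substitution_sites`` positions
    taken evenly across the reporter; each position contributes one
    transition (to the ref base's transition partner) and one transversion.
    Transversions matching the mutator's signature change get the signature
    efficiency (they are the strand-biased class). Indel channels sit in the
    reporter's homonucleotide A-runs. Hotspots replace the background channel
    at their (position, change) with ``multiplier`` times the background
    rate, optionally restricted to one orientation. Refractory sites have
    efficiency 0 while the ATT3 flank is present.
    """
    cfg = default_model_config()
    if config:
        cfg = {**cfg, **config}
    locus = locus if locus is not None else default_locus()
    seq = locus.orf_sequence
    n_sub = int(cfg["n_substitution_sites"])
    class_rates = cfg["class_rates"]
    class_eff = cfg["class_efficiencies"]
    for name, value in class_eff.items():
        if not 0 <= value <= 1:
            raise ValidationError(f"class efficiency {name} outside [0, 1]")

    # evenly spaced substitution positions, skipping the start codon
    positions = np.unique(
        np.linspace(10, len(seq) - 10, n_sub).round().astype(int)
    )
    hotspot_keys = {(h["position"], h["change"]) for h in cfg.get("hotspots", [])}
    hotspot_positions = {h["position"] for h in cfg.get("hotspots", [])}
    positions = [p for p in positions if p not in hotspot_positions]
    for hp in sorted(hotspot_positions):
        positions.append(hp)  # hotspot positions always carry channels
    positions = sorted(set(positions))

    ts_rate = class_rates["transition"] / len(positions)
    tv_rate = class_rates["transversion"] / len(positions)
    signature = cfg.get("signature_change")
    sites: list[SiteError] = []
    for pos in positions:
        if pos in hotspot_positions:
            continue  # hotspot positions carry only their dedicated channel
        ref = seq[pos - 1]
        ts = f"{ref}>{TRANSITION_PARTNER[ref]}"
        tv = f"{ref}>{TRANSVERSION_PARTNER[ref]}"
        if (pos, ts) not in hotspot_keys:
            sites.append(SiteError(pos, ts, ts_rate, class_eff["transition"]))
        if (pos, tv) not in hotspot_keys:
            if signature and tv == signature:
                eff = cfg["signature_efficiency"]
                sites.append(SiteError(pos, tv, tv_rate, eff))
                extra = float(cfg.get("signature_or1_multiplier", 1.0)) - 1.0
                if extra > 0:
                    sites.append(
                        SiteError(pos, tv, extra * tv_rate, eff, (Orientation.OR1,))
                    )
            else:
                sites.append(SiteError(pos, tv, tv_rate, class_eff["transversion"]))

    for h in cfg.get("hotspots", []):
        orientations = tuple(
            Orientation(o) for o in h.get("orientations", ["OR1", "OR2"])
        )
        base = tv_rate if ">" in h["change"] else class_rates["single_deletion"]
        sites.append(
            SiteError(
                h["position"],
                h["change"],
                float(h["multiplier"]) * base,
                float(h.get("efficiency", class_eff["transversion"])),
                orientations,
            )
        )

    runs = [(lo, seq[lo - 1]) for lo, hi in REPORTER_A_RUNS]
    del_rate = class_rates["single_deletion"] / len(runs)
    ins_rate = class_rates["single_insertion"] / len(runs)
    for lo, base in runs:
        sites.append(SiteError(lo, f"del:{base}", del_rate, class_eff["single_deletion"]))
        sites.append(SiteError(lo, f"ins:{base}", ins_rate, class_eff["single_insertion"]))

    refractory = frozenset(
        (r["position"], r["change"]) for r in cfg.get("refractory_sites", [])
    )
    return ErrorModel(
        mutator=cfg["mutator"],
        strand_role=StrandRole(cfg["strand_role"]),
        sites=tuple(sites),
        refractory_sites=refractory,
        no_orf_change_fraction=float(cfg["no_orf_change_fraction"]),
    )


# ---------------------------------------------------------------------------
# study design and simulation


@dataclass(frozen=True)
class StrainSpec:
    name: str
    mmr_status: MmrStatus
    orientation: Orientation
    att_variant: str = "ATT3"
    polymerase: str = "pol2-M644G"
    strand_role: StrandRole = StrandRole.LEADING


@dataclass(frozen=True)
class StudyDesign:
    """Which strains to simulate and at what depth."""

    strains: tuple[StrainSpec, ...]
    n_cultures: int = 24
    n_final: int = 2**22
    n_sequenced: int = 250
    seed: int = 0
    culture_wise: bool = False  # sample sequenced mutants per culture (siblings)

    def __post_init__(self) -> None:
        deficient = [s for s in self.strains if s.mmr_status is MmrStatus.DEFICIENT]
        for d in deficient:
            partner = [
                s
                for s in self.strains
                if s.mmr_status is MmrStatus.PROFICIENT
                and s.orientation == d.orientation
                and s.polymerase == d.polymerase
                and s.att_variant == d.att_variant
            ]
            if not partner:
                raise ValidationError(
                    f"deficient strain {d.name} has no MMR-proficient partner "
                    "with matching orientation"
                )


def default_design(
    seed: int = 0,
    n_cultures: int = 24,
    n_final: int = 2**22,
    n_sequenced: int = 250,
    include_att0: bool = False,
    orientations: tuple[Orientation, ...] = BOTH_ORIENTATIONS,
) -> StudyDesign:
    """Paired proficient/msh2-null strains in both orientations (and
    optionally the ATT0 orientation-1 pair)."""
    strains: list[StrainSpec] = []
    for orientation in orientations:
        for status in (MmrStatus.PROFICIENT, MmrStatus.DEFICIENT):
            tag = "MSH2" if status is MmrStatus.PROFICIENT else "msh2"
            strains.append(
                StrainSpec(
                    name=f"pol2-M644G_{tag}_{orientation.value}",
                    mmr_status=status,
                    orientation=orientation,
                )
            )
    if include_att0:
        for status in (MmrStatus.PROFICIENT, MmrStatus.DEFICIENT):
            tag = "MSH2" if status is MmrStatus.PROFICIENT else "msh2"
            strains.append(
                StrainSpec(
                    name=f"pol2-M644G_{tag}_OR1_ATT0",
                    mmr_status=status,
                    orientation=Orientation.OR1,
                    att_variant="ATT0",
                )
            )
    return StudyDesign(
        strains=tuple(strains),
        n_cultures=n_cultures,
        n_final=n_final,
        n_sequenced=n_sequenced,
        seed=seed,
    )


@dataclass
class StudyDataset:
    """Everything one simulated study produced, plus its truth table."""

    model: ErrorModel
    design: StudyDesign
    loci: dict[str, ReporterLocus]  # keyed by strain name
    experiments: dict[str, FluctuationExperiment]
    spectra: dict[str, Spectrum]
    truth: dict

    def write(self, outdir: str | Path) -> Path:
        """Write the dataset in the pipeline's input dialects.

        Layout: ``reporter_<ATT>.fasta``, ``strains.tsv`` (manifest),
        ``counts.tsv``, ``spectra/<strain>.tsv`` and ``truth.json``.
        """
        outdir = Path(outdir)
        (outdir / "spectra").mkdir(parents=True, exist_ok=True)

        variants = {spec.att_variant for spec in self.design.strains}
        for variant in sorted(variants):
            locus = next(
                self.loci[s.name]
                for s in self.design.strains
                if s.att_variant == variant
            )
            write_reporter_fasta(
                locus.orf_sequence,
                outdir / f"reporter_{variant}.fasta",
                label=f"synthetic-reporter-{variant}",
            )

        with open(outdir / "strains.tsv", "w") as fh:
            cols = [
                "strain", "polymerase", "mmr_status", "orientation",
                "att_variant", "strand_role", "n_final", "plating_fraction",
                "n_sequenced", "fasta", "spectrum",
            ]
            fh.write("\t".join(cols) + "\n")
            for spec in self.design.strains:
                exp = self.experiments[spec.name]
                fh.write(
                    "\t".join(
                        [
                            spec.name,
                            spec.polymerase,
                            spec.mmr_status.value,
                            spec.orientation.value,
                            spec.att_variant,
                            spec.strand_role.value,
                            repr(exp.n_final),
                            repr(exp.plating_fraction),
                            str(self.spectra[spec.name].n_sequenced),
                            f"reporter_{spec.att_variant}.fasta",
                            f"spectra/{spec.name}.tsv",
                        ]
                    )
                    + "\n"
                )

        with open(outdir / "counts.tsv", "w") as fh:
            fh.write("experiment_label\tculture_index\tmutant_count\n")
            for spec in self.design.strains:
                for i, c in enumerate(self.experiments[spec.name].counts):
                    fh.write(f"{spec.name}\t{i}\t{c}\n")

        for spec in self.design.strains:
            write_spectrum(self.spectra[spec.name], outdir / "spectra" / f"{spec.name}.tsv")

        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)
        return outdir


def _sample_spectrum(
    model: ErrorModel,
    spec: StrainSpec,
    n_sequenced: int,
    rng: np.random.Generator,
    experiment: Optional[FluctuationExperiment] = None,
    culture_wise: bool = False,
) -> Spectrum:
    active = model.sites_for(spec.orientation, spec.mmr_status, spec.att_variant)
    rates = np.array([r for _, r in active])
    if rates.sum() <= 0:
        raise ValidationError(f"strain {spec.name}: no active error channels")
    probs = rates / rates.sum()

    n_noc = int(rng.binomial(n_sequenced, model.no_orf_change_fraction))
    n_orf = n_sequenced - n_noc

    if culture_wise and experiment is not None:
        # extreme sibling scenario: every sequenced mutant from the same
        # culture shares that culture's dominant mutation channel
        counts = np.asarray(experiment.counts, dtype=float)
        if counts.sum() == 0:
            chosen = rng.choice(len(active), size=n_orf, p=probs)
        else:
            culture_sites = rng.choice(len(active), size=len(counts), p=probs)
            cultures = rng.choice(
                len(counts), size=n_orf, p=counts / counts.sum()
            )
            chosen = culture_sites[cultures]
        site_counts = np.bincount(chosen, minlength=len(active))
    else:
        site_counts = rng.multinomial(n_orf, probs)

    records: list[MutationRecord] = []
    k = 0
    for (site, _), count in zip(active, site_counts):
        for _ in range(int(count)):
            k += 1
            records.append(
                site.to_record(
                    mutant_id=f"{spec.name}-m{k:04d}",
                    strain=spec.name,
                    mmr_status=spec.mmr_status,
                    orientation=spec.orientation,
                )
            )
    return Spectrum(
        records=tuple(records),
        n_sequenced=n_sequenced,
        n_no_orf_change=n_noc,
        strain=spec.name,
        mmr_status=spec.mmr_status,
        orientation=spec.orientation,
    )


def simulate_study(model: ErrorModel, design: StudyDesign) -> StudyDataset:
    """Simulate fluctuation assays and sequenced spectra for every strain.

    Mutant counts and spectra are sampled independently (the spectrum is a
    multinomial draw conditional on being a resistant mutant) unless
    ``design.culture_wise`` is set, in which case sequenced mutants inherit
    their culture's dominant mutation channel — the extreme sibling
    scenario, for sensitivity analysis. Fully reproducible from
    ``design.seed``.
    """
    root = np.random.SeedSequence(design.seed)
    strain_seeds = root.spawn(len(design.strains))

    loci: dict[str, ReporterLocus] = {}
    experiments: dict[str, FluctuationExperiment] = {}
    spectra: dict[str, Spectrum] = {}
    truth_strains: dict[str, dict] = {}

    for spec, seed_seq in zip(design.strains, strain_seeds):
        rng = np.random.default_rng(seed_seq)
        locus = default_locus(spec.orientation, spec.att_variant)
        loci[spec.name] = locus
        total = model.total_rate(spec.orientation, spec.mmr_status, spec.att_variant)
        exp = simulate_cultures(
            rate=total,
            n_final=design.n_final,
            n_cultures=design.n_cultures,
            seed=rng,
            label=spec.name,
        )
        experiments[spec.name] = exp
        spectra[spec.name] = _sample_spectrum(
            model, spec, design.n_sequenced, rng, exp, design.culture_wise
        )
        truth_strains[spec.name] = {
            "total_rate": total,
            "m": total * design.n_final,
            "orientation": spec.orientation.value,
            "mmr_status": spec.mmr_status.value,
            "att_variant": spec.att_variant,
        }

    truth = {
        "strains": truth_strains,
        "expected_class_cfs": {
            att: model.expected_class_cfs(att)
            for att in sorted({s.att_variant for s in design.strains})
        },
        "expected_site_cfs": {
            att: {
                str(pos): {
                    o.value: model.expected_site_cf(pos, o, att)
                    for o in BOTH_ORIENTATIONS
                    if model.expected_site_cf(pos, o, att) is not None
                }
                for pos in HOTSPOT_POSITIONS
            }
            for att in sorted({s.att_variant for s in design.strains})
        },
        "no_orf_change_fraction": model.no_orf_change_fraction,
        "seed": design.seed,
    }
    return StudyDataset(
        model=model,
        design=design,
        loci=loci,
        experiments=experiments,
        spectra=spectra,
        truth=truth,
    )
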