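"""End-to-end analysis pipeline: rates -> spectra -> mismatch inference ->
correction factors -> significance, from a study directory to a report.

A study directory (as written by :func:`strandmmr.simulate.StudyDataset.write`
or assembled by hand from real data) contains:

* ``strains.tsv`` — one row per strain: labels, orientation, ATT variant,
  strand role, cells per culture, sequencing depth, and paths to the
  reporter FASTA and the spectrum TSV;
* ``counts.tsv`` — per-culture mutant counts keyed by strain label;
* the referenced FASTA and spectrum files.

The pipeline estimates each strain's mutation rate, pairs each msh2-null
strain with its MMR-proficient partner (same polymerase, orientation and ATT
variant), computes class correction factors with bootstrap significance,
combines orientations by geometric mean, and writes a self-describing JSON
report plus a flat TSV summary. Every stochastic step is seeded from the
single configuration seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import repair, spectra as spectra_mod
from .errors import ValidationError
from .fluctuation import (
    FluctuationExperiment,
    RateEstimate,
    estimate_rate,
    rate_confidence_interval,
)
from .reporter import (
    MmrStatus,
    Orientation,
    ReporterLocus,
    StrandRole,
    build_reporter,
    read_reporter_fasta,
)
from .spectra import ClassSelector, Spectrum, read_spectrum, standard_selectors

logger = logging.getLogger("strandmmr")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_study"]


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration for one pipeline run."""

    study_dir: Path
    outdir: Optional[Path] = None
    estimator: str = "mss_mle"
    include_no_orf_change: bool = True
    n_resamples: int = 1000
    seed: Optional[int] = None
    alpha: float = 0.05
    ci_level: float = 0.95
    censor_at: Optional[int] = 10_000
    site_positions: tuple[int, ...] = ()  # extra per-site correction factors

    def __post_init__(self) -> None:
        object.__setattr__(self, "study_dir", Path(self.study_dir))
        if self.outdir is not None:
            object.__setattr__(self, "outdir", Path(self.outdir))
        if self.n_resamples > 0 and self.seed is None:
            raise ValidationError(
                "bootstrap significance is enabled (n_resamples > 0) but no "
                "seed was given; set seed or n_resamples=0"
            )
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "site_positions" in raw:
            raw["site_positions"] = tuple(raw["site_positions"])
        return cls(**raw)


@dataclass
class StrainData:
    name: str
    polymerase: str
    mmr_status: MmrStatus
    orientation: Orientation
    att_variant: str
    strand_role: StrandRole
    locus: ReporterLocus
    experiment: FluctuationExperiment
    spectrum: Spectrum
    rate: Optional[RateEstimate] = None


@dataclass
class PipelineResult:
    report: dict
    strains: dict[str, StrainData]

    def combined_cf(self, selector_name: str, polymerase: str | None = None,
                    att_variant: str = "ATT3") -> Optional[dict]:
        for entry in self.report["combined"]:
            if entry["selector"] != selector_name or entry["att_variant"] != att_variant:
                continue
            if polymerase is not None and entry["polymerase"] != polymerase:
                continue
            return entry
        return None


def load_study(config: PipelineConfig) -> dict[str, StrainData]:
    """Read and validate every input of a study directory."""
    study = config.study_dir
    manifest_path = study / "strains.tsv"
    if not manifest_path.exists():
        raise ValidationError(f"no strain manifest at {manifest_path}")
    manifest = pd.read_csv(manifest_path, sep="\t", dtype=str)

    counts_path = study / "counts.tsv"
    counts = pd.read_csv(counts_path, sep="\t", comment="#")
    counts_by_label = {
        label: grp.sort_values("culture_index")["mutant_count"].astype(int).tolist()
        for label, grp in counts.groupby("experiment_label")
    }

    loci_cache: dict[tuple[str, str], ReporterLocus] = {}
    strains: dict[str, StrainData] = {}
    for _, row in manifest.iterrows():
        name = row["strain"]
        orientation = Orientation(row["orientation"])
        key = (row["fasta"], orientation.value)
        if key not in loci_cache:
            loci_cache[key] = build_reporter(
                read_reporter_fasta(study / row["fasta"]), orientation
            )
        locus = loci_cache[key]
        if name not in counts_by_label:
            raise ValidationError(f"strain {name}: no cultures in {counts_path}")
        experiment = FluctuationExperiment(
            counts=tuple(counts_by_label[name]),
            n_final=float(row["n_final"]),
            plating_fraction=float(row.get("plating_fraction", 1.0)),
            label=name,
        )
        spectrum = read_spectrum(study / row["spectrum"], locus)
        strains[name] = StrainData(
            name=name,
            polymerase=row["polymerase"],
            mmr_status=MmrStatus(row["mmr_status"]),
            orientation=orientation,
            att_variant=row.get("att_variant", "ATT3"),
            strand_role=StrandRole(row.get("strand_role", "leading")),
            locus=locus,
            experiment=experiment,
            spectrum=spectrum,
        )
    return strains


def _selectors(config: PipelineConfig) -> list[ClassSelector]:
    sel = standard_selectors()
    for pos in config.site_positions:
        sel.append(spectra_mod.site(int(pos)))
    return sel


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis and (optionally) write report files.

    Returns the in-memory result; if ``config.outdir`` is set, also writes
    ``report.json`` and ``report.tsv`` there.
    """
    logger.info("loading study from %s", config.study_dir)
    strains = load_study(config)

    seed_root = np.random.SeedSequence(
        config.seed if config.seed is not None else 0
    )
    # stable per-purpose seed streams, independent of dict ordering
    names = sorted(strains)
    rate_seeds = dict(zip(names, seed_root.spawn(len(names))))

    for name in names:
        sd = strains[name]
        est = estimate_rate(
            sd.experiment,
            method=config.estimator,
            **({"censor_at": config.censor_at} if config.estimator == "mss_mle" else {}),
        )
        kwargs = {"censor_at": config.censor_at} if config.estimator == "mss_mle" else {}
        sd.rate = rate_confidence_interval(
            est,
            sd.experiment,
            level=config.ci_level,
            seed=np.random.default_rng(rate_seeds[name]),
            **kwargs,
        )
        logger.info(
            "rate[%s] = %.3g (%s; m=%.3g; CI %.3g-%.3g)",
            name, sd.rate.rate, sd.rate.method, sd.rate.m,
            sd.rate.ci_low, sd.rate.ci_high,
        )

    # pair msh2-null strains with their proficient partners
    pairs = []
    for name in names:
        sd = strains[name]
        if sd.mmr_status is not MmrStatus.DEFICIENT:
            continue
        partners = [
            p
            for p in strains.values()
            if p.mmr_status is MmrStatus.PROFICIENT
            and p.polymerase == sd.polymerase
            and p.orientation == sd.orientation
            and p.att_variant == sd.att_variant
        ]
        if not partners:
            raise ValidationError(
                f"deficient strain {name} has no MMR-proficient partner "
                f"({sd.polymerase}, {sd.orientation.value}, {sd.att_variant})"
            )
        pairs.append((sd, partners[0]))
    if not pairs:
        raise ValidationError("no deficient/proficient strain pairs in the study")

    selectors = _selectors(config)
    pair_seeds = seed_root.spawn(len(pairs))
    pair_entries = []
    for (deficient, proficient), pair_seed in zip(pairs, pair_seeds):
        selector_seeds = pair_seed.spawn(len(selectors))
        classes = []
        for selector, sel_seed in zip(selectors, selector_seeds):
            entry = _class_entry(
                deficient, proficient, selector, config, sel_seed
            )
            classes.append(entry)
        pair_entries.append(
            {
                "deficient": deficient.name,
                "proficient": proficient.name,
                "polymerase": deficient.polymerase,
                "orientation": deficient.orientation.value,
                "att_variant": deficient.att_variant,
                "strand_role": deficient.strand_role.value,
                "classes": classes,
            }
        )

    combined = _combine_pairs(pair_entries, config)

    report = {
        "config": {
            "study_dir": str(config.study_dir),
            "estimator": config.estimator,
            "include_no_orf_change": config.include_no_orf_change,
            "n_resamples": config.n_resamples,
            "seed": config.seed,
            "alpha": config.alpha,
            "ci_level": config.ci_level,
            "censor_at": config.censor_at,
            "p_value_method": "parametric bootstrap (binomial counts, "
            "lognormal rates, add-one smoothing)",
        },
        "rates": {
            name: {
                "rate": strains[name].rate.rate,
                "m": strains[name].rate.m,
                "ci_low": strains[name].rate.ci_low,
                "ci_high": strains[name].rate.ci_high,
                "ci_level": strains[name].rate.ci_level,
                "method": strains[name].rate.method,
                "n_cultures": strains[name].experiment.n_cultures,
                "n_final": strains[name].experiment.n_final,
            }
            for name in names
        },
        "pairs": pair_entries,
        "combined": combined,
    }

    if config.outdir is not None:
        config.outdir.mkdir(parents=True, exist_ok=True)
        with open(config.outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
        _write_tsv(report, config.outdir / "report.tsv")
        logger.info("report written to %s", config.outdir)
    return PipelineResult(report=report, strains=strains)


def _class_entry(deficient, proficient, selector, config, seed_seq):
    locus = deficient.locus
    cr_def = spectra_mod.partition_rate(
        deficient.rate, deficient.spectrum, selector, locus,
        config.include_no_orf_change,
    )
    cr_prof = spectra_mod.partition_rate(
        proficient.rate, proficient.spectrum, selector, proficient.locus,
        config.include_no_orf_change,
    )
    entry = {
        "selector": selector.name,
        "count_deficient": cr_def.count,
        "count_proficient": cr_prof.count,
        "rate_deficient": cr_def.rate,
        "rate_proficient": cr_prof.rate,
    }
    if cr_prof.count == 0:
        entry.update(cf=None, note="no proficient observations; factor undefined")
        return entry
    cf = repair.class_correction_factor(cr_def, cr_prof)
    entry.update(
        cf=cf.value,
        cf_display=cf.display_value,
        is_upper_bound=cf.is_upper_bound,
    )
    if config.n_resamples > 0:
        p, ci = repair.cf_significance(
            deficient.spectrum,
            deficient.rate,
            proficient.spectrum,
            proficient.rate,
            selector,
            locus,
            n_resamples=config.n_resamples,
            seed=np.random.default_rng(seed_seq),
            include_no_orf_change=config.include_no_orf_change,
        )
        entry.update(
            p_value=p,
            significant=bool(p <= config.alpha),
            ci_low=ci[0],
            ci_high=ci[1],
        )
    return entry


def _combine_pairs(pair_entries: list[dict], config: PipelineConfig) -> list[dict]:
    """Geometric-mean combination of per-orientation correction factors for
    pairs sharing (polymerase, ATT variant)."""
    groups: dict[tuple[str, str], list[dict]] = {}
    for pair in pair_entries:
        groups.setdefault((pair["polymerase"], pair["att_variant"]), []).append(pair)

    combined = []
    for (polymerase, att), group in sorted(groups.items()):
        by_selector: dict[str, list[dict]] = {}
        for pair in group:
            for entry in pair["classes"]:
                by_selector.setdefault(entry["selector"], []).append(
                    {**entry, "orientation": pair["orientation"]}
                )
        for selector_name, entries in by_selector.items():
            cfs = [
                repair.CorrectionFactor(
                    value=e["cf"],
                    is_upper_bound=e.get("is_upper_bound", False),
                    selector_name=selector_name,
                )
                for e in entries
                if e.get("cf")
            ]
            if not cfs:
                combined.append(
                    {
                        "polymerase": polymerase,
                        "att_variant": att,
                        "selector": selector_name,
                        "cf": None,
                        "note": "undefined in every orientation",
                    }
                )
                continue
            if len(cfs) == 1:
                cf = dataclasses.replace(cfs[0], single_orientation=len(entries) > 1)
            else:
                cf = cfs[0]
                for other in cfs[1:]:
                    cf = repair.combine_orientations(cf, other)
            eff = repair.repair_efficiency(cf)
            combined.append(
                {
                    "polymerase": polymerase,
                    "att_variant": att,
                    "selector": selector_name,
                    "cf": cf.value,
                    "cf_display": cf.display_value,
                    "is_upper_bound": cf.is_upper_bound,
                    "single_orientation": cf.single_orientation,
                    "efficiency_pct": eff.percent,
                    "efficiency_below_one": eff.below_one,
                    "orientations": [e["orientation"] for e in entries if e.get("cf")],
                    "p_values": {
                        e["orientation"]: e.get("p_value") for e in entries
                    },
                }
            )
    return combined


def _write_tsv(report: dict, path: Path) -> None:
    rows = []
    for entry in report["combined"]:
        rows.append(
            {
                "polymerase": entry["polymerase"],
                "att_variant": entry["att_variant"],
                "selector": entry["selector"],
                "cf": entry.get("cf"),
                "cf_display": entry.get("cf_display"),
                "is_upper_bound": entry.get("is_upper_bound"),
                "single_orientation": entry.get("single_orientation"),
                "efficiency_pct": entry.get("efficiency_pct"),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def configure_logging(verbose: bool = False) -> None:
    """Log to stderr so result streams stay pipeable."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)
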