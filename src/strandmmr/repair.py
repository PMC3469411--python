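"""MMR correction factors and repair-efficiency arithmetic.

The apparent efficiency of mismatch repair for a mutation class is measured
by the correction factor: the class mutation rate in an MMR-deficient
(msh2-null) strain divided by the same class rate in the MMR-proficient
partner strain. A correction factor of 250 means that, on average, 249 of
250 replication errors of that class are removed by MMR, i.e. the fraction
repaired is ``1 - 1/CF``.

Conventions implemented here:

* zero observations on the deficient side are raised to one and the factor
  flagged as an upper bound ("<=");
* factors measured in the two reporter orientations are combined by
  geometric mean (ratios of rates multiply, so their natural average is
  geometric);
* when only one orientation has observations, its factor is reported alone
  and flagged single-orientation;
* significance and interval estimates come from a seeded parametric
  bootstrap over the sequencing counts and the rate uncertainties, because
  counts and rates are measured on very different designs (multinomial
  spectra vs fluctuation assays) and no closed form covers both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .errors import EstimatorError, ValidationError
from .reporter import ReporterLocus
from .spectra import ClassRate, ClassSelector, Spectrum, partition_rate

__all__ = [
    "CorrectionFactor",
    "RepairEfficiency",
    "correction_factor",
    "class_correction_factor",
    "combine_orientations",
    "repair_efficiency",
    "cf_significance",
    "round_sigfigs",
]


def round_sigfigs(x: float, sigfigs: int = 2) -> float:
    """Round to significant figures (summary display convention)."""
    if x == 0 or not math.isfinite(x):
        return x
    exponent = math.floor(math.log10(abs(x)))
    return round(x, -exponent + sigfigs - 1)


@dataclass(frozen=True)
class CorrectionFactor:
    """Ratio of an MMR-deficient class rate to the MMR-proficient one."""

    value: float
    is_upper_bound: bool = False
    single_orientation: bool = False
    p_value: Optional[float] = None
    ci: Optional[tuple[float, float]] = None
    selector_name: str = ""
    rate_deficient: Optional[float] = None
    rate_proficient: Optional[float] = None
    count_deficient: Optional[int] = None
    count_proficient: Optional[int] = None

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValidationError("correction factor must be >= 0")

    @property
    def display_value(self) -> float:
        """Two-significant-figure value used in summaries."""
        return round_sigfigs(self.value, 2)


@dataclass(frozen=True)
class RepairEfficiency:
    """Fraction of mismatches of a class removed by MMR: ``1 - 1/CF``."""

    fraction: float
    below_one: bool = False  # CF < 1: no apparent repair, efficiency floored at 0

    @property
    def percent(self) -> float:
        return 100.0 * self.fraction

    @property
    def percent_rounded(self) -> int:
        return round(self.percent)


def correction_factor(
    rate_deficient: float,
    rate_proficient: float,
    count_deficient: Optional[int] = None,
    count_proficient: Optional[int] = None,
    pseudocount_rate: Optional[float] = None,
    selector_name: str = "",
) -> CorrectionFactor:
    """Compute a correction factor from a pair of class rates.

    ``count_deficient``/``count_proficient`` are the underlying spectrum
    counts when known. A deficient count of zero invokes the upper-bound
    rule: the count is raised to one, so the rate becomes
    ``pseudocount_rate`` (the rate one observation would imply, i.e. total
    rate / sequenced denominator) and the result is flagged ``<=``. The rule
    applies only on the deficient side; a proficient rate of zero leaves the
    factor undefined.
    """
    if rate_proficient <= 0 or (count_proficient is not None and count_proficient < 1):
        raise EstimatorError(
            "no MMR-proficient observations for this class; the correction "
            "factor is undefined"
        )
    if rate_deficient < 0:
        raise ValidationError("rates must be non-negative")
    is_upper_bound = False
    if count_deficient == 0:
        if pseudocount_rate is None:
            raise ValidationError(
                "deficient count is 0: supply pseudocount_rate (total rate / "
                "sequenced denominator) to apply the upper-bound rule"
            )
        rate_deficient = pseudocount_rate
        count_deficient = 1
        is_upper_bound = True
    return CorrectionFactor(
        value=rate_deficient / rate_proficient,
        is_upper_bound=is_upper_bound,
        selector_name=selector_name,
        rate_deficient=rate_deficient,
        rate_proficient=rate_proficient,
        count_deficient=count_deficient,
        count_proficient=count_proficient,
    )


def class_correction_factor(
    deficient: ClassRate, proficient: ClassRate
) -> CorrectionFactor:
    """Correction factor from two :class:`~strandmmr.spectra.ClassRate` values
    for the same selector (deficient first)."""
    if deficient.selector_name != proficient.selector_name:
        raise ValidationError(
            f"selector mismatch: {deficient.selector_name} vs "
            f"{proficient.selector_name}"
        )
    return correction_factor(
        rate_deficient=deficient.rate,
        rate_proficient=proficient.rate,
        count_deficient=deficient.count,
        count_proficient=proficient.count,
        pseudocount_rate=deficient.unit_rate,
        selector_name=deficient.selector_name,
    )


def combine_orientations(
    cf_or1: Optional[CorrectionFactor],
    cf_or2: Optional[CorrectionFactor],
) -> CorrectionFactor:
    """Geometric-mean average of the two orientations' correction factors.

    If one orientation has no defined factor (no observations), the other is
    returned flagged single-orientation. Upper-bound flags propagate.
    """
    if cf_or1 is None and cf_or2 is None:
        raise EstimatorError("no correction factor defined in either orientation")
    if cf_or1 is None or cf_or2 is None:
        present = cf_or1 if cf_or1 is not None else cf_or2
        return replace(present, single_orientation=True)
    if cf_or1.value <= 0 or cf_or2.value <= 0:
        raise ValidationError("geometric-mean averaging requires positive factors")
    return CorrectionFactor(
        value=math.sqrt(cf_or1.value * cf_or2.value),
        is_upper_bound=cf_or1.is_upper_bound or cf_or2.is_upper_bound,
        selector_name=cf_or1.selector_name or cf_or2.selector_name,
    )


def repair_efficiency(cf: CorrectionFactor | float) -> RepairEfficiency:
    """Fraction of errors repaired implied by a correction factor.

    ``1 - 1/CF``; a factor below one means no apparent repair and returns
    efficiency 0 with a flag. Monotone increasing in CF with limit 1.
    """
    value = getattr(cf, "value", cf)
    if value == 0:
        raise ValidationError("correction factor of 0 has no repair efficiency")
    if value < 1:
        return RepairEfficiency(fraction=0.0, below_one=True)
    return RepairEfficiency(fraction=1.0 - 1.0 / value)


def _lognormal_sd_from_ci(rate_estimate) -> float:
    """Log-scale standard deviation implied by an estimate's CI (0 if none)."""
    lo = getattr(rate_estimate, "ci_low", None)
    hi = getattr(rate_estimate, "ci_high", None)
    if not lo or not hi or lo <= 0 or hi <= lo:
        return 0.0
    level = getattr(rate_estimate, "ci_level", None) or 0.95
    from scipy.stats import norm

    z = norm.ppf(0.5 + level / 2)
    return (math.log(hi) - math.log(lo)) / (2 * z)


def cf_significance(
    spectrum_deficient: Spectrum,
    rate_deficient,
    spectrum_proficient: Spectrum,
    rate_proficient,
    selector: ClassSelector,
    locus: ReporterLocus,
    n_resamples: int = 2000,
    seed: int | np.random.Generator = 0,
    include_no_orf_change: bool = True,
) -> tuple[float, tuple[float, float]]:
    """Parametric-bootstrap p-value and CI for a class correction factor.

    Each resample redraws the class count in each strain as
    Binomial(n_sequenced, observed fraction) and each overall rate from the
    lognormal distribution implied by its confidence interval; zero counts in
    a resample are raised to one (mirroring the upper-bound rule) so every
    resampled factor is finite. The two-sided p-value for the null CF = 1 is
    ``2 * min(P(CF* <= 1), P(CF* >= 1))`` with add-one smoothing; the CI is
    the 95% percentile interval of the resampled factors.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    cr_def = partition_rate(
        rate_deficient, spectrum_deficient, selector, locus, include_no_orf_change
    )
    cr_prof = partition_rate(
        rate_proficient, spectrum_proficient, selector, locus, include_no_orf_change
    )
    if cr_prof.count == 0:
        raise EstimatorError(
            "no MMR-proficient observations for this class; significance "
            "undefined"
        )

    n_def, n_prof = cr_def.denominator, cr_prof.denominator
    counts_def = rng.binomial(n_def, cr_def.count / n_def, size=n_resamples)
    counts_prof = rng.binomial(n_prof, cr_prof.count / n_prof, size=n_resamples)
    counts_def = np.maximum(counts_def, 1)
    counts_prof = np.maximum(counts_prof, 1)

    r_def = getattr(rate_deficient, "rate", rate_deficient)
    r_prof = getattr(rate_proficient, "rate", rate_proficient)
    sd_def = _lognormal_sd_from_ci(rate_deficient)
    sd_prof = _lognormal_sd_from_ci(rate_proficient)
    rates_def = r_def * np.exp(rng.normal(0.0, sd_def, size=n_resamples)) if sd_def else np.full(n_resamples, r_def)
    rates_prof = r_prof * np.exp(rng.normal(0.0, sd_prof, size=n_resamples)) if sd_prof else np.full(n_resamples, r_prof)

    cf_star = (rates_def * counts_def / n_def) / (rates_prof * counts_prof / n_prof)
    n_le = int(np.sum(cf_star <= 1.0))
    n_ge = int(np.sum(cf_star >= 1.0))
    p = 2.0 * min((n_le + 1) / (n_resamples + 1), (n_ge + 1) / (n_resamples + 1))
    p = min(p, 1.0)
    lo, hi = np.quantile(cf_star, [0.025, 0.975])
    return p, (float(lo), float(hi))
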