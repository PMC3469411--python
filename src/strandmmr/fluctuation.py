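"""Fluctuation-assay simulation and mutation-rate estimation.

A fluctuation assay grows many parallel cultures from small inocula and
scores the number of selectable mutants per culture (here, 5-FOA-resistant
clones that have lost reporter function). Because a mutation arising early in
a culture's growth leaves many mutant descendants, the per-culture counts
follow the heavy-tailed Luria-Delbruck distribution rather than a Poisson.
The quantity estimated is ``m``, the expected number of mutation events per
culture; the mutation rate per cell division is ``m / N_t`` with ``N_t`` the
number of cells per culture at plating.

Three standard estimators are provided:

* ``p0`` — from the fraction of cultures with zero mutants,
  ``m = -ln(p0)``;
* Lea-Coulson method of the median — solves ``median/m - ln(m) = 1.24``;
* Ma-Sandri-Sarkar (MSS) maximum likelihood — the default; uses the MSS
  recursion for the Luria-Delbruck pmf,
  ``p_0 = exp(-m)``, ``p_r = (m/r) * sum_{i=0}^{r-1} p_i / (r - i + 1)``.

Confidence intervals are profile-likelihood for the MLE and a seeded
nonparametric bootstrap over cultures for the other two estimators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import EstimatorError, ValidationError

__all__ = [
    "FluctuationExperiment",
    "RateEstimate",
    "simulate_cultures",
    "luria_delbruck_pmf",
    "estimate_rate_p0",
    "estimate_rate_lc_median",
    "estimate_rate_mss_mle",
    "estimate_rate",
    "lea_coulson_m",
    "rate_confidence_interval",
]

CHI2_95_1DF = stats.chi2.ppf(0.95, df=1)  # profile-likelihood cutoff


@dataclass(frozen=True)
class FluctuationExperiment:
    """Mutant counts from parallel cultures plus cells per culture."""

    counts: tuple[int, ...]
    n_final: float
    plating_fraction: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.counts) < 2:
            raise ValidationError("a fluctuation experiment needs >= 2 cultures")
        if any(c < 0 for c in self.counts):
            raise ValidationError("mutant counts must be non-negative")
        if self.n_final <= 0 or self.n_final < max(self.counts):
            raise ValidationError(
                "n_final must be positive and at least the largest count"
            )
        if not 0 < self.plating_fraction <= 1:
            raise ValidationError("plating_fraction must be in (0, 1]")
        object.__setattr__(self, "counts", tuple(int(c) for c in self.counts))

    @property
    def n_cultures(self) -> int:
        return len(self.counts)

    @property
    def p0(self) -> float:
        return sum(c == 0 for c in self.counts) / len(self.counts)


@dataclass(frozen=True)
class RateEstimate:
    """A mutation rate per cell division with its provenance."""

    rate: float
    m: float
    n_final: float
    method: str
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    ci_level: Optional[float] = None
    approximate: bool = False  # set when a plating-fraction adjustment applied

    def with_ci(self, lo: float, hi: float, level: float) -> "RateEstimate":
        return RateEstimate(
            rate=self.rate,
            m=self.m,
            n_final=self.n_final,
            method=self.method,
            ci_low=lo,
            ci_high=hi,
            ci_level=level,
            approximate=self.approximate,
        )


def simulate_cultures(
    rate: float,
    n_final: int,
    n_cultures: int,
    seed: int | np.random.Generator,
    founder: int = 1,
    plating_fraction: float = 1.0,
    label: str = "",
) -> FluctuationExperiment:
    """Simulate a fluctuation assay by generation-wise doubling.

    Each culture grows from ``founder`` cells to ``n_final`` by synchronous
    doublings (``n_final`` must be a power-of-two multiple of ``founder``).
    At each doubling, every wild-type cell divides; each division yields one
    mutant daughter with probability ``rate``, so new mutant lineages per
    generation are Binomial(wild-type cells, rate). Mutant lineages double
    deterministically (no death, no fitness cost) — the classical
    Luria-Delbruck assumptions. The expected number of mutation events per
    culture is ``rate * (n_final - founder)``, i.e. ``m ~= rate * N_t``.
    """
    if rate < 0:
        raise ValidationError("mutation rate must be >= 0")
    if n_cultures < 1:
        raise ValidationError("need at least one culture")
    ratio = n_final / founder
    generations = round(math.log2(ratio))
    if founder < 1 or 2**generations != ratio:
        raise ValidationError(
            "n_final must be a power-of-two multiple of the founder count"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    wt = np.full(n_cultures, founder, dtype=np.int64)
    mut = np.zeros(n_cultures, dtype=np.int64)
    for _ in range(generations):
        new = rng.binomial(wt, rate) if rate > 0 else 0
        wt = 2 * wt - new
        mut = 2 * mut + new
    if plating_fraction < 1.0:
        mut = rng.binomial(mut, plating_fraction)
    return FluctuationExperiment(
        counts=tuple(int(c) for c in mut),
        n_final=float(n_final),
        plating_fraction=plating_fraction,
        label=label,
    )


def luria_delbruck_pmf(m: float, r_max: int) -> np.ndarray:
    """Luria-Delbruck pmf ``p_0 .. p_{r_max}`` via the MSS recursion."""
    if m < 0:
        raise ValidationError("m must be >= 0")
    p = np.zeros(r_max + 1)
    p[0] = math.exp(-m)
    if r_max == 0:
        return p
    # weights w[d] = 1 / (d + 1) for distance d = r - i, d = 1..r_max
    w = 1.0 / (np.arange(1, r_max + 1) + 1.0)
    for r in range(1, r_max + 1):
        # sum_{i=0}^{r-1} p_i / (r - i + 1)
        p[r] = (m / r) * float(np.dot(p[:r], w[r - 1 :: -1]))
    return p


def _adjust_for_plating(m: float, plating_fraction: float) -> tuple[float, bool]:
    if plating_fraction >= 1.0:
        return m, False
    return m / plating_fraction, True


def estimate_rate_p0(experiment: FluctuationExperiment) -> RateEstimate:
    """Rate from the zero-count fraction: ``m = -ln(p0)``."""
    p0 = experiment.p0
    if p0 == 0:
        raise EstimatorError(
            "no zero-count cultures: the p0 estimator is out of range "
            "(use the median or MSS maximum-likelihood estimator)"
        )
    m = -math.log(p0)
    m, approx = _adjust_for_plating(m, experiment.plating_fraction)
    return RateEstimate(
        rate=m / experiment.n_final,
        m=m,
        n_final=experiment.n_final,
        method="p0",
        approximate=approx,
    )


LEA_COULSON_CONSTANT = 1.24


def lea_coulson_m(median: float) -> float:
    """Solve ``median/m - ln(m) = 1.24`` for ``m`` (bracketed root-finding)."""
    if median <= 0:
        raise EstimatorError("Lea-Coulson equation needs a positive median")

    def f(m: float) -> float:
        return median / m - math.log(m) - LEA_COULSON_CONSTANT

    # f is strictly decreasing in m; bracket the root
    lo = 1e-12
    hi = max(median, 1.0)
    while f(hi) > 0:
        hi *= 2
    return optimize.brentq(f, lo, hi, rtol=1e-9)


def estimate_rate_lc_median(experiment: FluctuationExperiment) -> RateEstimate:
    """Lea-Coulson method of the median: solve ``median/m - ln(m) = 1.24``."""
    median = float(np.median(experiment.counts))
    if median <= 0:
        raise EstimatorError(
            "median mutant count is 0: use the p0 estimator instead"
        )
    m = lea_coulson_m(median)
    m, approx = _adjust_for_plating(m, experiment.plating_fraction)
    return RateEstimate(
        rate=m / experiment.n_final,
        m=m,
        n_final=experiment.n_final,
        method="lc_median",
        approximate=approx,
    )


def _loglik_factory(counts: Sequence[int], max_count: int, censor_at: Optional[int]):
    """Return (loglik(m), effective counts) with optional right-censoring.

    Counts at or above ``censor_at`` contribute the log tail probability
    ``P(X >= censor_at)`` instead of a point mass — the proper likelihood for
    jackpot cultures whose exact count is immaterial.
    """
    counts = np.asarray(counts, dtype=np.int64)
    if counts.max(initial=0) > max_count and censor_at is None:
        raise EstimatorError(
            f"count {counts.max()} exceeds the pmf cap {max_count}; raise "
            "max_count or set censor_at to treat jackpots as right-censored"
        )
    if censor_at is not None:
        censored = counts >= censor_at
        exact = counts[~censored]
        n_cens = int(censored.sum())
        r_max = int(max(exact.max(initial=0), censor_at))
    else:
        exact = counts
        n_cens = 0
        r_max = int(exact.max(initial=0))
    uniq, mult = np.unique(exact, return_counts=True)

    def loglik(m: float) -> float:
        if m < 0:
            return -np.inf
        if m == 0:
            return 0.0 if (uniq.max(initial=0) == 0 and n_cens == 0) else -np.inf
        p = luria_delbruck_pmf(m, r_max)
        with np.errstate(divide="ignore"):
            ll = float(np.dot(mult, np.log(p[uniq])))
        if n_cens:
            tail = max(1.0 - float(p[:censor_at].sum()), 1e-300)
            ll += n_cens * math.log(tail)
        return ll

    return loglik


def estimate_rate_mss_mle(
    experiment: FluctuationExperiment,
    max_count: int = 100_000,
    censor_at: Optional[int] = None,
) -> RateEstimate:
    """Ma-Sandri-Sarkar maximum-likelihood estimate of ``m``.

    ``censor_at`` treats counts at or above that value as right-censored
    jackpots (their exact size carries almost no information about ``m`` but
    dominates the cost of the pmf recursion). Counts above ``max_count`` with
    no censoring raise, signalling that truncation is required.
    """
    counts = np.asarray(experiment.counts, dtype=np.int64)
    if counts.max(initial=0) == 0:
        m = 0.0
    else:
        loglik = _loglik_factory(counts, max_count, censor_at)
        # bracket: m near the Lea-Coulson scale, search on log grid
        res = optimize.minimize_scalar(
            lambda x: -loglik(math.exp(x)),
            bounds=(math.log(1e-8), math.log(max(counts.mean(), 1.0) * 10 + 10)),
            method="bounded",
            options={"xatol": 1e-10},
        )
        m = math.exp(res.x)
    m, approx = _adjust_for_plating(m, experiment.plating_fraction)
    return RateEstimate(
        rate=m / experiment.n_final,
        m=m,
        n_final=experiment.n_final,
        method="mss_mle",
        approximate=approx,
    )


def _profile_interval(
    experiment: FluctuationExperiment,
    m_hat: float,
    level: float,
    max_count: int,
    censor_at: Optional[int],
) -> tuple[float, float]:
    counts = np.asarray(experiment.counts, dtype=np.int64)
    cutoff = stats.chi2.ppf(level, df=1) / 2.0
    if counts.max(initial=0) == 0:
        # all-zero data: one-sided bound as if one pseudo-mutant were seen
        n = len(counts)
        upper = -math.log(1 - 1 / n) if n > 1 else 1.0
        return 0.0, upper
    loglik = _loglik_factory(counts, max_count, censor_at)
    ll_hat = loglik(m_hat)

    def g(m: float) -> float:
        return loglik(m) - (ll_hat - cutoff)

    lo_bracket = m_hat
    step = 0.5
    while g(lo_bracket * step) > 0 and lo_bracket * step > 1e-12:
        lo_bracket *= step
    lo = (
        optimize.brentq(g, lo_bracket * step, m_hat, rtol=1e-6)
        if lo_bracket * step > 1e-12
        else 0.0
    )
    hi_bracket = m_hat
    while g(hi_bracket * 2) > 0:
        hi_bracket *= 2
    hi = optimize.brentq(g, m_hat, hi_bracket * 2, rtol=1e-6)
    return lo, hi


def rate_confidence_interval(
    estimate: RateEstimate,
    experiment: FluctuationExperiment,
    level: float = 0.95,
    n_resamples: int = 2000,
    seed: int | np.random.Generator = 0,
    max_count: int = 100_000,
    censor_at: Optional[int] = None,
) -> RateEstimate:
    """Attach a confidence interval to a rate estimate.

    MSS maximum-likelihood estimates get a profile-likelihood interval
    (chi-square 1-df cutoff). p0 estimates get a binomial interval for the
    zero-culture count (Wilson score bounds on p0, mapped through
    ``m = -ln p0``); the zero-count fraction over a couple of dozen cultures
    is far too discrete for a resampling interval to hold its level.
    Median estimates get a
    seeded nonparametric bootstrap over cultures (percentile interval).
    Returns a copy of the estimate with the interval filled in.
    """
    if not 0 < level < 1:
        raise ValidationError("confidence level must be in (0, 1)")
    if estimate.method == "mss_mle":
        lo_m, hi_m = _profile_interval(
            experiment, estimate.m, level, max_count, censor_at
        )
        return estimate.with_ci(
            lo_m / experiment.n_final, hi_m / experiment.n_final, level
        )

    counts = np.asarray(experiment.counts, dtype=np.int64)
    n = len(counts)
    if counts.max(initial=0) == 0:
        upper = -math.log(1 - 1 / n) / experiment.n_final if n > 1 else np.nan
        return estimate.with_ci(0.0, upper, level)

    if estimate.method == "p0":
        n_zero = int((counts == 0).sum())
        p0_lo, p0_hi = stats.binomtest(n_zero, n).proportion_ci(
            confidence_level=level, method="wilson"
        )
        lo_m = -math.log(p0_hi)
        hi_m = -math.log(p0_lo) if p0_lo > 0 else math.inf
        lo_m, _ = _adjust_for_plating(max(lo_m, 0.0), experiment.plating_fraction)
        hi_m, _ = _adjust_for_plating(hi_m, experiment.plating_fraction)
        return estimate.with_ci(
            min(lo_m / experiment.n_final, estimate.rate),
            max(hi_m / experiment.n_final, estimate.rate),
            level,
        )

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if estimate.method != "lc_median":
        raise ValidationError(f"unknown estimator method {estimate.method!r}")
    boot = np.empty(n_resamples)
    for b in range(n_resamples):
        resample = counts[rng.integers(0, n, size=n)]
        med = float(np.median(resample))
        if med <= 0:
            # resample degenerated to a zero median: p0-style fallback
            nz = int((resample == 0).sum())
            m = -math.log(max(nz, 0.5) / n)
        else:
            m = lea_coulson_m(med)
        m, _ = _adjust_for_plating(m, experiment.plating_fraction)
        boot[b] = m / experiment.n_final
    alpha = (1 - level) / 2
    lo, hi = np.quantile(boot, [alpha, 1 - alpha])
    lo = min(lo, estimate.rate)
    hi = max(hi, estimate.rate)
    return estimate.with_ci(float(lo), float(hi), level)


def estimate_rate(
    experiment: FluctuationExperiment,
    method: str = "mss_mle",
    **kwargs,
) -> RateEstimate:
    """Dispatch to a named estimator (``p0``, ``lc_median`` or ``mss_mle``)."""
    estimators = {
        "p0": estimate_rate_p0,
        "lc_median": estimate_rate_lc_median,
        "mss_mle": estimate_rate_mss_mle,
    }
    try:
        fn = estimators[method]
    except KeyError:
        raise ValidationError(f"unknown estimator method {method!r}") from None
    return fn(experiment, **kwargs)
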