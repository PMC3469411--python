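"""Estimate a spontaneous mutation rate from a fluctuation assay.

Simulates 24 parallel cultures grown to ~17 million cells at a true rate of
2e-7 mutations per cell division, then estimates the rate three ways. The
per-culture mutant counts are Luria-Delbruck distributed (note the jackpot),
and each estimator returns the expected mutations per culture (m) and the
rate m / N_t with a 95% confidence interval.
"""

from strandmmr import (
    estimate_rate,
    rate_confidence_interval,
    simulate_cultures,
)

TRUE_RATE = 2e-7
N_FINAL = 2**24  # ~1.7e7 cells per culture at plating

experiment = simulate_cultures(
    rate=TRUE_RATE, n_final=N_FINAL, n_cultures=24, seed=20121011
)
print(f"mutant counts: {sorted(experiment.counts)}")
print(f"true rate: {TRUE_RATE:.2e} (m = {TRUE_RATE * N_FINAL:.2f})\n")

for method in ("p0", "lc_median", "mss_mle"):
    est = estimate_rate(experiment, method=method)
    est = rate_confidence_interval(est, experiment, seed=1)
    print(
        f"{method:9s} rate = {est.rate:.2e}  m = {est.m:.2f}  "
        f"95% CI [{est.ci_low:.2e}, {est.ci_high:.2e}]"
    )

print(
    "\nThe MSS maximum-likelihood estimate (the default) uses every count;"
    "\nthe p0 method uses only the zero-count fraction and the Lea-Coulson"
    "\nmethod only the median. With 24 cultures the estimates scatter around"
    "\nthe true rate and each 95% interval covers it in about 19 of 20"
    "\nrepeated assays (here the MSS interval narrowly misses - jackpot-"
    "\ndominated draws do that about 1 time in 20)."
)
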