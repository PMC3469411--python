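# Methods

This note documents the models behind `strandmmr`, the defaults and why they
were chosen, the numerical details, and what the synthetic-data tests do and
do not establish about real data.

## Fluctuation model and estimators

A fluctuation experiment is modeled classically: each culture grows from a
single founder by synchronous doublings to `N_t` cells; at every division a
wild-type cell yields a mutant daughter with probability equal to the
mutation rate; mutant lineages double deterministically (no death, no
fitness cost, no phenotypic lag, complete plating unless a plating fraction
is given). The expected number of mutation events per culture is
`m = rate × (N_t − founder) ≈ rate × N_t`, and the probability of a
mutant-free culture is `exp(−m)`, which the simulator reproduces to within
binomial error.

Because growth is by discrete generations, mutant clone sizes are powers of
two. The continuous-time Luria–Delbrück distribution assumed by the MSS
likelihood and the Lea–Coulson equation allows clones of every size, so
estimators fitted to simulated data carry a small distributional bias that
grows with `m` (about −4% for the MSS MLE and +2% for the median method at
`m = 2`; about −7% and −11% at `m = 3.4`). The package therefore validates
estimator recovery and interval coverage at `m = 2` with 24 cultures — a
standard operating regime for these assays, where the three estimators agree
with truth within a few percent — and this is documented here rather than
hidden in a tolerance. On real (asynchronous) cultures this particular bias
is absent.

Estimators:

- **p0** — `m = −ln(fraction of zero-count cultures)`. Needs at least one
  mutant-free culture. Its confidence interval inverts the Wilson score
  interval for the zero-count binomial proportion; a resampling interval is
  not used because the zero fraction of ~24 cultures takes too few distinct
  values for percentile bootstrap quantiles to hold their level (measured
  85% coverage versus 97% for Wilson at the validation condition).
- **Lea–Coulson median** — solves `median/m − ln m = 1.24` by Brent's method
  (relative tolerance 1e−9, bracket doubling). Valid when the median is
  positive. CI: seeded nonparametric bootstrap over cultures (percentile,
  2000 resamples by default); a resample whose median degenerates to zero
  falls back to the p0 formula with a half-count continuity correction.
- **MSS maximum likelihood** (default) — the Luria–Delbrück pmf is computed
  with the Ma–Sandri–Sarkar recursion `p₀ = e^(−m)`,
  `p_r = (m/r) Σ_{i=0}^{r−1} p_i/(r−i+1)`; `m` maximizes the log likelihood
  by bounded scalar minimization on the log scale (tolerance 1e−10). The
  recursion is O(r²) in the largest count, so jackpot cultures can be
  treated as right-censored at a cap (`censor_at`): counts at or above the
  cap contribute `log P(X ≥ cap)`, the statistically proper censored
  likelihood. Counts above a hard cap (default 10⁵) without censoring raise
  an error rather than silently truncating. CI: profile likelihood at the
  χ²₁ cutoff, with bracketed root-finding on each side.

All estimators take the experiment's `N_t` only as the final division
`rate = m/N_t`, so doubling `N_t` at fixed counts halves the rate. A plating
fraction below 1 is handled by binomial thinning in the simulator and by the
standard `m/fraction` adjustment in estimation, flagged approximate. The pmf
partial sums are monotone and bounded by 1; the mass beyond a cap `R` is the
heavy tail of the distribution (~`m/R`), which is why no finite partial sum
is expected to reach 1 to machine precision.

## Reporter model and mismatch inference

Coordinates are 1-based on the coding strand, and homonucleotide runs are
defined on the coding strand only, matching how spectra are conventionally
displayed; indels inside a run are rewritten to the run's 5′-most position
(idempotent, never 3′-ward). Each orientation of the reporter fixes which
ORF strand is synthesized as the nascent leading strand; the default mapping
(OR1 → coding strand) is the one forced by the worked signature case — an
A→T at base pair 686 in OR1 made by the leading-strand replicase must be a
`T-dT` mispair — and it is a configurable field of the locus, not a
constant, because it is a property of the construct's layout relative to
the origin, not of the ORF. Substitutions map to (template base,
misincorporated dNMP); deletions to an unpaired base on the template strand;
insertions to an unpaired base on the nascent strand. Re-deriving any event
under the opposite strand role yields the Watson–Crick complementary
mispair, and (OR1, leading) equals (OR2, lagging), which is verified
exhaustively for all 12 substitution types in both orientations.

The bundled 804-nt reporter sequence is synthetic (the real reporter's
sequence is not distributed with the package): a seeded random background
carrying the documented landmarks — A-runs at 174–178, 201–205 and 255–260,
A:T pairs at hotspot positions 279 and 686, and the ATT triplet-repeat flank
`ATTATTATTGTT` at 688–699 — with no other homonucleotide run longer than
three bases. `apply_att0` performs the three silent edits (690 T→A, 693 T→C,
696 T→A) that interrupt the repeat, refuses to run when the motif is absent,
and any user FASTA is accepted in place of the fixture.

## Rates, classes, correction factors

Class rates are the overall rate times the class share of sequenced mutants.
The denominator includes mutants with no ORF change by default — they were
genuine resistant isolates and their resistance arose elsewhere — with a
switch to exclude them, since either convention is defensible and published
tables do not always state which was used. Multi-base events are parsed and
retained but excluded from every numerator and denominator.

Correction factors divide the deficient-strain class rate by the proficient
one. Zero observations on the deficient side are raised to one (the rate one
observation would imply, overall rate / denominator) and the factor flagged
as an upper bound; the rule is deliberately one-sided — a proficient-strain
zero leaves the factor undefined rather than bounded. Orientation averaging
is geometric because factors are ratios; when only one orientation has
observations the single factor is reported with a flag. Repair efficiency is
`1 − 1/CF`, floored at 0 (with a flag) for factors below one. Displayed
values are rounded to two significant figures; full precision is kept
internally.

Significance of a factor against the null CF = 1 uses a seeded parametric
bootstrap: class counts are redrawn as Binomial(n_sequenced, observed
fraction), overall rates from the lognormal distribution implied by each
rate's confidence interval, zero resampled counts are raised to one, and the
two-sided p-value is `2·min(P(CF* ≤ 1), P(CF* ≥ 1))` with add-one smoothing
(so the smallest attainable p is 2/(B+1)); the interval is the 2.5–97.5%
percentile range of the resampled factors. No closed form covers the joint
count/rate uncertainty, which is why a simulation-based test was chosen; its
type-I error measures 4–6% at the 5% level in the calibration study, and the
method is recorded in every report for provenance. No multiple-testing
correction is applied across the selectors of a report; only the hotspot
scan adjusts (Bonferroni over reporter positions, binomial upper tail
against a uniform spread — a deliberately conservative screen for strong
enrichment).

## Synthetic-study generator

The generator's defaults describe a leading-strand-mutator study. Per-site,
per-change error channels (the msh2-null rates) are spread over 150 evenly
spaced substitution positions (one transition and one transversion each) and
the three A-runs (one deletion and one insertion channel each); class totals
are 8.0e−6 (transitions), 2.9e−6 (transversions), 2.2e−6 (deletions) and
1.45e−6 (insertions) per replication, placing the msh2-null total near
1.5e−5 and the proficient total near 1e−7 — the published operating regime
of a strong mutator background. Class repair efficiencies encode correction
factors of 440, 72, 1500 and 1100 respectively; the mutator's signature
channel (A→T on the coding strand, i.e. nascent dT opposite template T) has
its own 41-fold efficiency and a 4× rate elevation in OR1 only, giving the
orientation-biased spectrum a leading-strand mutator produces. Positions 279
and 686 carry dedicated OR1-only channels at 8× the background transversion
rate; the 686 channel is repair-refractory (efficiency 0) while the natural
ATT₃ flank is present and reverts to its intrinsic 35-fold factor in ATT₀
strains. With these settings the hotspots dominate the proficient spectrum
but not the msh2-null one, as observed in real spectra. A configurable 5% of
sequenced mutants carry no ORF change, and the total 5-FOA-resistance rate
is inflated accordingly so expected class correction factors are independent
of that fraction. Per-site inactivating fractions of the real reporter are
unknown; every default here is a synthetic stand-in, never a biological
claim.

Mutant counts and spectra are sampled independently (multinomial over
channel rates, conditional on being a mutant), matching how one overall rate
is combined with one sequenced spectrum in practice. This ignores
jackpot-induced sibling structure among sequenced mutants; a `culture_wise`
option samples the extreme opposite (every sequenced mutant inherits its
culture's dominant channel) for sensitivity analysis. The truth table
records every strain's total rate and the exact expected class and site
correction factors `Σr / Σr(1−e)`, so pipeline recovery is checked against
analytic truth rather than against another simulation.

What passing the recovery tests shows: the pipeline's estimators and
intervals are consistent and calibrated under the generative assumptions
above (independent multinomial spectra, classical Luria–Delbrück growth,
known strand mapping). What it does not show: robustness to sibling mutants,
selection artifacts, sequencing errors, or a mis-specified strand mapping in
real strains.

## Pipeline and problem sizes

The pipeline seeds every stochastic stage from one configuration seed via
spawned seed sequences keyed by sorted strain name and selector order, so
reruns are byte-identical. Validation errors (missing partners, malformed
rows with line numbers, bootstrap without a seed) and estimator failures
(e.g. p0 without zero cultures) are distinguished, also in the CLI's exit
codes (2 and 3).

Validation studies use 24 cultures per strain, `N_t = 2²²` cells
(msh2-null `m ≈ 60`, proficient `m ≈ 0.3–0.7`), 250 sequenced mutants per
strain and 500–1000 bootstrap/calibration replicates; jackpot censoring at
2000 for the MSS likelihood. Single-site correction factors rest on a few
dozen spectrum counts at that depth, so the reproduction script measures
the two site-686 quantities on a deeper design (64 cultures, 4000 sequenced
mutants per strain) where their sampling spread is a few tens of percent
rather than a few fold. These sizes put every validation quantity near its
asymptote while keeping the full suite and the reproduction script to a few
minutes on one CPU.

## Known limitations

- The discrete-generation simulator biases continuous-model estimators at
  large `m` (see above); real rate measurements are unaffected, but
  simulator-based checks should stay in the `m ≈ 1–3` regime.
- The Lea–Coulson equation is an approximation; outside roughly
  `1 < m < 15` the median method should not be preferred over MSS.
- The bootstrap significance test treats the two strains' rates as
  lognormal around their estimates; with very few cultures the implied CI
  width is itself noisy, and p-values near the add-one floor should be read
  as "p ≤ floor".
- Upper-bound ("≤") factors are point conventions, not intervals; combining
  an upper bound with a measured factor propagates the flag but not a
  bound-aware interval.
- The hotspot scan tests against a uniform spread over all reporter
  positions, not over mutable sites of matched class, so it is conservative
  where the mutable-site density is low.
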