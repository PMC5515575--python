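# Methods

This note documents the statistical procedures implemented in `lifespans`,
the assumptions behind them, the calibration of the synthetic cohorts, and
the numerical choices that matter when reproducing results.

## Scope and data model

The package analyses per-animal lifespan tables from factorial rodent
longevity experiments: each record carries an age at death (days), genotype
(`dwarf`/`control`), treatment (`GH`/`saline`), sex, and an event flag.
Censoring is supported throughout the survival machinery for generality, but
the maximum-lifespan test, the aging-rate estimator and the linear models
require fully observed deaths — the setting they were designed for, where
every animal is followed to death. Ages are stored as reals in days;
simulated times keep sub-day resolution by default because rounding to whole
days creates ties that change the behaviour of rank tests (a `round_to_days`
output option exists when tie-rich data are wanted deliberately).

## Survival estimation and testing

**Kaplan–Meier.** The product-limit estimator
S(t) = ∏_{t_i ≤ t} (1 − d_i/n_i) over distinct death times, with the
standard convention that censored animals leave the risk set after their
censoring age. With no censoring this reduces exactly to the empirical
survival function. The median lifespan is the smallest observed death time
with S(t) ≤ 0.5; this is the usual KM median convention and, for uncensored
data, a sample-median convention (for even n it picks the lower of the two
central order statistics when S hits 0.5 exactly).

**Log-rank.** At each distinct death time with d deaths among n at risk
(n_a in group A), the observed A-deaths are compared with the conditional
hypergeometric mean d·n_a/n and variance d·(n_a/n)(1 − n_a/n)(n − d)/(n − 1);
the variance term is defined as 0 when n = 1, where the (n − 1) denominator
degenerates. The statistic (O_A − E_A)²/ΣV is referred to χ²(1). Only the
two-group test is provided; multi-group contrasts go through the Cox model.
P-values are reported unadjusted — no multiple-testing correction is
applied anywhere in the package.

**Cox proportional hazards.** The partial likelihood is maximised by
Newton–Raphson with step-halving on likelihood decrease. Tied death times
use Efron's correction by default (day-resolution lifespan data are
tie-rich and Breslow attenuates coefficients toward zero in that regime;
Breslow is available for cross-checks). Convergence is declared when either
the max-norm of the score drops below 1e-8 or the Newton decrement
(scoreᵀ·I⁻¹·score, the estimated log-likelihood gap to the optimum) drops
below 1e-14 nats — the second criterion matters for n in the hundreds,
where the score's floating-point noise floor sits above the absolute
tolerance while the parameters are already converged to ~1e-8. Monotone
partial likelihoods (a covariate that perfectly separates the event order)
produce diverging coefficients; fits whose coefficients exceed 15 in
absolute value are flagged not-converged with a warning rather than raised,
since the direction of divergence is still informative. Standard errors
come from the inverse observed information at the optimum. The Rao score
test at β = 0 is exposed separately; with a binary covariate and no ties it
reproduces the log-rank chi-square algebraically, which the test suite
asserts to 1e-8.

**Linear lifespan models.** Lifespan in days is regressed on treatment with
sex as an optional covariate (ordinary least squares, delegated to
statsmodels). "Adjusted mean lifespan" per treatment arm is the model
prediction at that arm averaged over the cohort's observed sex
distribution; in a saturated one-factor model these equal the sample group
means exactly. Rank-deficient designs are rejected with the collinear
columns named.

## Maximum-lifespan (quantile-threshold) test

To compare maximum rather than typical lifespan, the two groups are pooled
and the threshold age is the ⌈n(1 − q)⌉-th pooled order statistic, the age
at which only the fraction q (0.25 or 0.10 in practice) of animals remains
alive. Each animal is scored alive (age strictly greater than the
threshold) or dead; ties at the threshold count as dead, because the
threshold animal itself has died by that age — a deterministic rule under
rounded-day ties. The 2×2 group × status table is tested with a two-sided
Fisher exact test computed by direct hypergeometric enumeration in integer
arithmetic: with margins fixed, the p-value sums the probabilities of all
tables whose probability does not exceed the observed one (the
"probability-mass at most observed" two-sided rule; a configurable relative
slack, default 1e-7, admits near-ties for compatibility with floating-point
implementations, though the enumeration itself is exact). The odds ratio is
(a·d)/(b·c), infinite when b·c = 0 < a·d, undefined (NaN) on a zero margin,
where p = 1.

Pooling is over the two compared groups only, not the whole study, because
comparisons are made within genotype. The test is exact and therefore
conservative: its null rejection rate at nominal α = 0.05 with n = 30 + 30
and q = 0.25 is nearer 1–2% (the acceptance suite measures it). Its value
over log-rank is confined to alternatives whose effect lives in the upper
tail; the test suite exercises a median-matched crossing-hazard scenario
(hazard raised ×1.9 before the 30%-mortality age, lowered after, so the
median is unchanged but the upper tail diverges) where it rejects more
often than log-rank at the same nominal α. For alternatives that shift the
whole curve, log-rank is the more powerful of the two — both are provided
for exactly this reason.

## Interval mortality and aging rates

Mortality in half-open 200-day age intervals [k·200, (k+1)·200), anchored
at day 0, is estimated occurrence/exposure style: deaths in the interval
divided by the mouse-days lived in it (an animal alive at the interval
start contributes min(death age, interval end) − start). Person-time and
death counts are conserved exactly by construction, which the suite asserts.
To guard against sparse tails, the last death-containing
interval is excluded when it holds exactly one death. The aging rate
between adjacent usable intervals is their rate difference divided by the
distance between interval midpoints (= the width for uniform bins),
reported at the shared boundary age and scaled to deaths per 10,000 mice
per day. The absolute difference is the default; a signed variant is provided because falls in mortality are
otherwise indistinguishable from rises. Gaps in the usable sequence break
the difference series rather than entering as zero rates.

Two estimand subtleties are worth recording. First, the large-n limit of
the occurrence/exposure rate over [s, e) is the *exposure-weighted* average
hazard (S(s) − S(e)) / ∫ₛᵉ S(t)dt, not the unweighted time-average of h —
the two agree while S ≈ 1 and split apart late in life when S collapses
within a bin. The consistency tests compare against the exposure-weighted
form, which is what the estimator actually converges to. Second, the
finite difference of interval averages is a biased estimate of the *point*
hazard slope when the hazard curves within a bin: for a Gompertz hazard
a·e^{bt} and bin width w, differencing exact unweighted bin averages
inflates the slope at the shared boundary by the factor
2(cosh(bw) − 1)/(bw)², ≈ 1.23 at b = 0.008/day and w = 200 days; at late
ages the exposure weighting pushes the bias in the opposite direction
(below 1) because deaths concentrate early in the bin. Only near the bulk
of the death distribution do the two distortions roughly cancel. The
estimator is therefore a good *qualitative* description of how mortality
accelerates — its intended use — but not a calibrated estimate of h′(t)
with 200-day bins at mouse-like b, and one acceptance check that asserts
pointwise slope recovery within 15% across all well-populated boundaries
fails for exactly this reason (kept failing deliberately; the magnitude of
the discrepancy is the bias computed above, not an implementation error).

## Synthetic cohorts

Lifespans are drawn from the Gompertz–Makeham law, hazard
h(t) = a·e^{bt} + c (per day), by exact inverse-CDF sampling:
u ~ U(0,1) is mapped through the closed-form quantile for c = 0 (with the
b = 0 exponential limit handled separately) and through a clamped Newton
inversion of the cumulative hazard otherwise. Sampling is bit-reproducible
given a seed; each design cell uses a substream keyed by (seed, cell), so
adding or removing a cell never perturbs the others' draws.

Effects enter as per-cell parameter sets rather than hazard multipliers so
crossing-hazard scenarios are expressible; `with_hazard_ratio` covers the
proportional case. The shipped `week1`/`week2` designs use b = 0.0077/day in
every cell — a mortality-rate doubling time of ≈ 90 days, typical of
laboratory mice — with per-cell a solved from the closed-form median so
that cell medians hit their targets. Targets reproduce the published group
medians where printed (dwarf saline vs GH pooled 1004 vs 839 days for the
week-1 protocol with group sizes 31/36; male medians 1011 vs 807; week-2
analogues 1019 vs ≈ 808 with the printed 22%/19.6% male/female drops) and
are calibration choices elsewhere (female and littermate-control cells),
solved so the sex-pooled medians land on the printed pooled values with
group sizes split evenly by sex, remainder to males. The designs are
calibration devices that mimic printed medians — they are *not* estimates
of the real cohorts: the study's raw lifespans are unpublished, so nothing
here constrains the true shape of those survival curves, their tie
structure, litter effects, or any non-Gompertz behaviour. Passing tests on
these cohorts demonstrate correctness of the estimators under a known law,
not reproduction of the study's data.

## Assay transforms

Three formula-defined transforms round out the pipeline. ΔΔCt fold change:
ΔCt = gene Ct − reference Ct per condition, ΔΔCt = ΔCt_treated −
ΔCt_normal, fold = 2^ΔΔCt under the `paper` convention (the default) or 2^(−ΔΔCt) under `livak` (the standard
convention, under which up-regulation gives fold > 1). The two are exact
reciprocals; the default's sign behaviour is deliberately surfaced in the
API docs because the printed formula is inverted relative to common usage
and figures reporting "fold change relative to control" do not resolve the
sign. Respiratory quotient is VCO₂/VO₂ (≈1.0 carbohydrate, ≈0.7 fat
oxidation). Insulin-tolerance-test glucose series are normalised to
percent of baseline (glucose-tolerance tests are left on the raw scale).

## Problem sizes used in checks

The consistency and calibration suites use: 10⁴–10⁵ draws for simulator
fidelity and aging-rate limits; 100 seeds for the KS pass-rate; 200
replicates of n = 500 for Cox recovery and coverage; 2000 replicates of
n = 30 + 30 for the exact test's size and power; 100 replicates of the
full 149-animal week-1 design for the calibrated-scenario check; and exhaustive
enumeration of all 2×2 tables with total ≤ 40 for the Fisher oracle. These
sizes make the Monte-Carlo error small relative to every asserted tolerance
while keeping the default test run fast.

## Known limitations

- No stratified, time-varying or frailty Cox models; no interval censoring;
  no left truncation (observation is assumed to start at birth).
- Two-group log-rank only; no trend or k-group variants.
- The aging-rate estimator inherits the discretization bias discussed
  above; interpret it qualitatively or choose bins with b·w ≪ 1.
- The Fisher test's two-sided rule is the probability-mass convention;
  Boschloo/Barnard-style unconditional tests are out of scope.
- The simulator offers no Weibull/log-normal alternatives and no
  heterogeneity (frailty) across animals beyond the factorial cells.
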