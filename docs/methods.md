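# Methods

## Decision model

Two strategies for potentially resectable pancreatic cancer are compared on
an intention-to-treat basis. Each is a chance tree over the treatment a
patient actually ends up receiving, with terminal cohorts valued in
life-months (LM) and quality-adjusted life-months (QALMs).

**Surgery-first (SF).** Resection is attempted with probability 0.94;
otherwise the patient receives exploratory surgery only. An attempted
resection is fatal (grade-5 complication) with probability 0.07 and then
accrues zero months — the only accrual rule consistent with the cohort
payoffs reproducing the intention-to-treat totals. Survivors split by margin
status (R0 conditionally 0.56) and receipt of adjuvant therapy (0.61). Severe
but non-fatal complications (grade 3–4, probability 0.22) and grade 3+
adjuvant toxicity (0.43) enter as explicit chance branches whose leaves share
the cohort's LM but carry degraded QALM variants — so they affect quality of
life, never survival, matching cohorts whose variants list identical months
with different QALMs.

**Neoadjuvant therapy (NAT).** After treatment and restaging: resection 0.41,
exploratory surgery 0.10, and the residual 0.49 no surgery at all. Resection
carries a 0.02 fatal-complication probability; survivors split R0/R1
(conditionally 0.29/0.71) with a 0.35 grade 3–4 complication branch.

The R0 probabilities are interpreted as *conditional on resection*: only
that reading makes the probability-weighted cohort payoffs reproduce the
published intention-to-treat totals (verified arithmetically in the tests).
The complements of the resection probabilities are not stated anywhere and
are forced by the baseline values: NAT no-surgery $=1-0.41-0.10$, SF
exploratory $=1-0.94$.

## Markov engine and evaluation modes

Terminal cohorts run a monthly three-state Markov model (alive disease-free,
alive with disease, dead) for up to 60 cycles. Death follows a constant
exponential hazard $\lambda = \ln 2 / m$; survival accrues as the
end-of-cycle alive occupancy, with no half-cycle correction and no
discounting (neither is needed to reproduce the printed totals). QALMs accrue
as alive occupancy times the utility of the phase in force.

Two evaluation modes:

* **direct** (default, used by the acceptance script): the published cohort
  payoffs are the leaf values, making the rollup an exact multilinear
  function of the transition probabilities.
* **trace**: each leaf is re-derived from the Markov trace. The exponential
  median is calibrated by bisection so that the truncated trace mean matches
  the cohort's months (`calibrate_median`; monotone, so bisection is exact to
  tolerance 1e-9), and QALMs follow a utility schedule: NAT cohorts 3 cycles
  of treatment at 0.81, one cycle of surgical recovery at 0.59 (0.48 under a
  grade 3–4 complication), adjuvant cohorts 6 cycles at 0.81 (0.53 under
  toxicity), remainder at 0.81; unresected cohorts 0.65 throughout. The flat
  0.65 schedule is validated by the unresectable cohort's printed
  10.86 months × 0.65 ≈ 7.06 QALMs; disease-free and with-disease states
  share the 0.81 stable-disease weight (only one such utility exists), so the
  states are distinguished in the trace but not in payoff.

Trace-mode LM agrees with direct mode by construction; trace-mode QALMs are
schedule-derived and agree with the printed values to within a few percent,
which is why direct mode is the reference for reproduction and trace mode the
engine for property tests and new analyses.

## Parameter synthesis

Proportions are pooled with the Freeman–Tukey double-arcsine transform and
DerSimonian–Laird random effects (τ² floored at zero; the canonical
moment-estimator pipeline for proportion meta-analysis). Back-transformation
uses Miller's inverse with the harmonic-mean sample size; the pooled sd on
the probability scale comes from the delta method (dp/dt ≈ sin 2t).
statsmodels' `combine_effects` serves as an independent cross-check in the
tests, never as the implementation.

Median survival is pooled on the hazard scale: $m_p = (\sum_i w_i/m_i)^{-1}$
with size weights. A formula printed as $(\sum_i w_i m_i)^{-1}$ appears in
some descriptions of this estimator but is dimensionally inconsistent
(1/months); the hazard-pooling form here is the one implied by averaging
exponential rate parameters and recomputing the median, and is what the
worked two-study example (medians 12 and 24 months, sizes 100 and 50 →
14.4 months) pins down.

## Deterministic sensitivity analysis

Any single transition probability can be overridden; the strategy's residual
branch absorbs the complement (NAT: no-surgery, exploratory held at
baseline; SF: exploratory). Indifference thresholds are located by bisection
on the SF−NAT difference to tolerance 1e-4, on the QALM objective by
default — the objective on which the two published resection thresholds
(≈ 51% NAT, ≈ 76% SF) are reproducible; on raw months the NAT threshold
moves up to ≈ 56%, a discrepancy check the tests assert. Sweeps run within
each parameter's reported study range. Two-way maps report the per-cell QALM
winner with a 0.01-QALM tie band.

## Probabilistic sensitivity analysis

10000 Monte Carlo iterations re-draw all twelve transition probabilities,
re-balance the residual branches, and re-evaluate both strategies. Three
sampling rules per parameter:

* **range** (default): uniform over the parameter's reported
  lowest-to-highest study range. This is the operative reading of sampling
  "from the entire range of the data distribution", and it reproduces the
  published PSA profile closely (SF mean ≈ 19.7 months, sd ≈ 2.7, below the
  baseline rollup because the baseline sits near the favourable ends of the
  SF ranges).
* **beta**: moment-matched beta (point estimate and sd), truncated to the
  reported range by inverse-CDF restriction; printed moments that are
  infeasible for a beta law fall back to uniform-over-range with a warning.
  Under this mode the printed sds concentrate essentially all variability in
  the SF arm (SF sd ≈ 1.1 vs NAT ≈ 0.2 months), but the truncated means sit
  at the baseline rollup rather than below it.
* **fitted**: the literal fitted parametric specifications (generalized
  extreme value, generalized Pareto, Johnson SB, Burr, Pearson 5,
  log-Pearson 3, Cauchy, Pareto 2), clamped to [0, 1]. Their parameters sit
  on a scale of ~10⁻² — two orders of magnitude below the baseline
  probabilities — and no transformation linking the two scales is stated, so
  this mode exists for inspection, not inference: under it both strategies
  collapse towards their unresected payoffs.

No single sampling rule can reproduce every published PSA summary
simultaneously: the published NAT mean (17.16 months) lies below the
baseline NAT rollup (20.22), which no mean-preserving sampling of a
multilinear rollup can produce, and the published SF range minimum
(5.57 months) is below any value the rollup can attain within the reported
parameter ranges. The default therefore targets the qualitative profile and
the SF summaries, which it matches almost exactly.

All draws flow from one seeded generator in a fixed parameter order, so the
sample stream — and every per-iteration output file — is reproducible bit
for bit. Survival payoffs stay at baseline during PSA (only the model
probabilities are sampled). The distribution toolbox implements 14 families
(the eight named above plus normal, lognormal, beta, gamma, Weibull,
exponential) with quantile/CDF inverse pairs verified to 1e-8, MLE fitting
with explicit convergence flagging, and Anderson–Darling selection; the
catalogue is an open extension point.

## Synthetic trial pools

The generator emulates the literature pool the parameters are pooled from:
50 studies of 11–121 patients (the observed size spread), binomial event
counts around true proportions with between-study heterogeneity injected on
the arcsine-square-root scale (τ = 0.05 by default, matching the scale the
pooling model works on, so recovery experiments are internally consistent),
and per-study medians drawn from the asymptotic normal law of a sample
median of exponential lifetimes, sd $= m/(\ln 2\,\sqrt n)$ (exact
order-statistic simulation available via a flag). A default true median of
17 months matches the pooled neoadjuvant-arm survival of the bundled pool
(≈ 15–17 months).

What passing recovery tests show: the pooling estimators are unbiased to
<1% for proportions (50 studies × 100 patients, 200 replicates) with CI
coverage near nominal, and recover true medians to a few percent (the
weighted harmonic mean is slightly biased low for noisy small-study
medians — a property of the estimator, not a bug). What they do not show:
robustness to publication bias, selective outcome reporting,
non-exponential survival, or correlated outcomes, none of which the
generator emulates.

## Numerical choices and limitations

* Bisection everywhere a root is needed (threshold search, median
  calibration): the objective is monotone or sign-changing by construction,
  and results are grid-independent.
* Chance-node probabilities are validated to 1e-9; occupancy conservation
  and monotone dead-state occupancy are asserted per cycle in the tests.
* The bundled uncertainty inputs contain one internal inconsistency (the SF
  grade 3–4 complication row's variance does not equal its sd²); the loader
  warns and trusts the sd.
* The model carries no costs (no cost-effectiveness ratios), no
  microsimulation, and no tornado-style ranking across all parameters; the
  two-strategy structure is fixed.
* The NAT grade-3+ toxicity probability parameterises the pathway but does
  not enter the payoff mixing (the published cohort variants carry no NAT
  toxicity branch), so it is inert in direct mode — the threshold search
  correctly reports "no threshold" for it.
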