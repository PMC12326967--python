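# Methods

## Structural and covariate model

Disposition is one-compartment with first-order elimination. For subject
*i* with weight WT (grams) and postmenstrual age PMA (weeks):

    CL_i = θ_CL · (WT/1000)^a · (PMA/30)^b · exp(η_i),   η_i ~ N(0, ω²)
    V_i  = θ_V · (WT/1000)^c

The packaged final model carries θ_CL = 0.0487 L/h, a = 0.919, b = 1.53,
ω² = 0.0188, θ_V = 0.497 L and c = 0.851. Volume is interpreted as **total
litres** with the allometric exponent on WT/1000: a superlinear per-kg
volume would be physiologically implausible in neonates, whereas a total
volume of ≈0.5 L/kg at 1 kg is consistent with the aminoglycoside
literature. BSV is carried on clearance only; the model supports a second
random effect on volume (`omega2_v`) but the final model fixes it at zero.

Residual error is combined proportional + additive,
y = C·(1+ε_p) + ε_a. The magnitudes are not identifiable from published
summaries, so the simulation defaults are σ_prop = 0.15 and
σ_add = 0.5 mg/L — typical aminoglycoside immunoassay behaviour — and are
configurable. Simulated concentrations that fall below zero are truncated
to zero (a count is logged); they are retained in estimation and excluded
from relative-error metrics.

Concentration under an arbitrary dosing history is the superposition of
closed-form terms: a zero-order infusion contributes
(R/CL)(1−e^{−k·t_e})·e^{−k·t_d} (t_e time infused, t_d time since the
infusion ended, k = CL/V); IM doses default to instantaneous complete
absorption (F = 1) since no absorption model is identifiable from TDM-style
sampling, with an optional first-order `ka_im` (Bateman term, with the
L'Hôpital limiting form used when ka ≈ k). Times are hours since first
dose; concentrations mg/L.

## Synthetic cohorts

The generator emulates the study conditions the analysis assumes.
Marginals are log-normal, parameterised by the reported median and IQR
(σ_log = ln(q75/q25)/1.349) and clipped to the reported min–max:

| quantity | median (IQR) | clip range |
|---|---|---|
| gestational age | 29 (26–31) wk | 23–41 wk |
| PMA at initiation | 45+6 (39+5–53+5) wk | 25+6–113+6 wk |
| weight at initiation | 1.34 (0.90–1.90) kg | 0.58–3.77 kg |
| serum creatinine | 43 (29–57) µmol/L | 15–91 µmol/L |

Only marginals are published; a Gaussian-copula correlation of ρ = 0.8
between gestational age and weight makes bigger babies the more mature
ones, and postnatal age is derived as PNA = 7·(PMA − GA) with PMA drawn
independently and floored at GA + 1 day. Dosing follows the institutional
protocol (11 mg/kg; q36h when PMA < 29 wk, else q24h; IV as 0.5 h
infusions), 5 doses per subject by default, with the IM fraction
defaulting to 0.5 (the source cohort's route mix is unreported; both arms
need data for route comparisons). Sampling is third-dose TDM — trough
30 min before dose 3, peak 30 min after the end of the IV infusion or
60 min after the IM injection — plus one "random" sample uniform in the
remainder of the third dosing interval, giving 3 observations/subject.
Optional uniform jitter (±15 min) on nominal TDM times is off by default.

What the generator does **not** emulate: charting errors, missed or
off-protocol doses, time-varying weight and creatinine, covariate
measurement error, informative sampling, or BQL reporting conventions
other than truncation at zero. Passing recovery and calibration tests
therefore demonstrate internal consistency of estimator and diagnostics
under the stated conditions, not robustness to real-world data artefacts.

## Estimation

The marginal likelihood is approximated by the Laplace method with
interaction: for each subject the joint −2 log density
q(η) = Σ_j [ln σ²_j(η) + r_j²/σ²_j(η)] + ηᵀΩ⁻¹η is minimised over η
(vectorised Newton iterations with finite-difference curvature, step
tolerance 1e−9, ≤60 iterations, backtracking), with the residual variance
evaluated at the conditional prediction; the OFV adds the log-determinant
curvature correction and all 2π constants, so with no random effects it
reduces exactly to the Gaussian −2 log-likelihood. This is an
approximation to first-order conditional estimation with interaction; the
package's accuracy claims rest on parameter recovery, not on matching any
other implementation's OFV values. Against 1-D adaptive quadrature of the
true marginal, the approximation agrees to ~1e−4 relative on
single-observation fixtures.

The outer problem maximises over (log θ, exponents, log ω², log σ) with
L-BFGS-B (numerical gradients, step 1e−6; gradient tolerance 1e−6;
≤500 iterations). Default initial values are generic neonatal
aminoglycoside figures (θ_CL = 0.1 L/h, θ_V = 0.5 L, allometric-style
exponents 0.75/1.0, ω² = 0.05, σ_prop = 0.2, σ_add = 0.3 mg/L); recovery
runs never start at the generating values. Standard errors come from the
central finite-difference Hessian of the OFV (cov = 2·H⁻¹, pseudo-inverse
if ill-conditioned), delta-transformed to the natural scale. Empirical
Bayes estimates are the per-subject posterior modes at the final
estimates; subjects without observations sit at the prior mode.

Stepwise covariate selection fits each candidate (power terms on
WT/GA/PMA/PNA/SCr; fixed-exponent allometric terms, 0.75 on CL and 1.0 on
V; a sigmoid-Emax maturation function PMA^γ/(TM50^γ+PMA^γ) for PMA on CL,
with γ and TM50 estimated) and accepts the largest OFV drop strictly
greater than 3.84; backward elimination then deletes, one at a time, the
included effect whose removal costs least, while that cost is ≤ 10.83.
Ties in forward addition break by candidate order. Normalisation
constants: WT/1000, PMA/30, GA/30, PNA/7, SCr/45 (cohort medians).
Non-converging candidate fits are skipped with a warning and recorded in
the selection trace.

## Diagnostics

**Prediction metrics.** PE_i = (PRED−OBS)/OBS·100; MPE% = median PE,
MAPE% = median |PE|, RMSE% = √mean(PE²), F20/F30 = % of |PE| within
20/30 (inclusive boundaries). Pass criteria: |MPE%| ≤ 15, MAPE% ≤ 30,
RMSE% < 15, F20 > 35, F30 > 50. Non-positive observations are excluded
with a logged count.

**pcVPC.** Observations and simulated replicates of the same design are
scaled by median(PRED in bin)/PRED (population prediction, η = 0) within
quantile bins of time-after-last-dose (≥10 observations per bin; default
up to 8 bins — the binning is a package choice, none being published).
Default percentile set 5/50/95 with simulation-based 95% bands
(2.5/50/97.5 supported via the `percentiles` argument). No LOQ
lower-bound correction is applied.

**NPDE.** Each subject's observation vector is decorrelated with the
Cholesky factor of the empirical covariance of its simulated replicates
(default 5,000; falls back to per-observation standardisation if the
covariance is singular), ranked within the decorrelated simulations and
mapped through Φ⁻¹. Two numerical choices matter with zero-truncated
data: ranks use randomised tie-breaking, pd = (#below + U·(1+#ties))/(K+1)
— the standard probability-integral-transform treatment of censored
atoms; and the observation is decorrelated in the same batched triangular
solve as the simulations so shared atoms remain exact ties in floating
point. pd is clipped away from 0/1 by 1/(2K). The battery is Wilcoxon
signed-rank (mean 0), a two-sided χ² variance test (variance 1) and
Shapiro–Wilk (fixed-seed subsample of 5,000 when larger, logged); the
global p is 3·min(p), capped at 1, with adequacy declared at p > 0.01.

**Bootstrap.** Whole subjects are resampled with replacement to the
original cohort size (no stratification), each replicate refit starting
from the reference estimates; medians and percentile 95% CIs are
reported, non-converged replicates excluded and counted, and the report
flagged unreliable if more than half fail. Default 2,000 replicates;
tests use 100–200.

## Regimen evaluation

Dose correctness: within ±5% (inclusive, float-robust) of 11 mg/kg of the
weight at initiation. Sampling appropriateness: troughs within 30 min
before a dose, peaks 60–90 min after the dose start (IM injection or IV
infusion initiation — the protocol's nominal peak draw at 60 min after a
30-min infusion's start coincides with 30 min after its end), both on or
after the third dose. Targets: peak 15–25 mg/L inclusive, trough strictly
< 5 mg/L. Route comparison uses the independent-sample t-test on levels
and χ² (Yates-corrected) on in-range proportions, switching to Fisher's
exact test when any expected cell count is ≤ 5.

## Problem sizes and reproducibility

Recovery experiments use five replicate cohorts per size (200 and 500
subjects, 3 observations each); NPDE calibration uses 200-subject cohorts
with 2,000 simulation replicates over 20 runs; bootstrap coverage uses
100-subject cohorts with 100 replicates over 15 repetitions (the
percentile bootstrap undercovers at much smaller cohorts, where the
weight-exponent estimator is heavy-tailed); pcVPC calibration uses
150-subject cohorts with 400 replicates. These sizes are
the package's scaled-down defaults for routine verification; the full-size
settings (2,000 bootstrap replicates, 5,000 NPDE simulations, 500 pcVPC
simulations) remain the library defaults. All randomness flows from
explicit integer seeds through `numpy.random.default_rng`; identical
seeds give bit-identical datasets and reports.

## Known limitations

- Two-compartment disposition, nonlinear elimination, covariate effects
  of co-medication and ω-blocks (correlated random effects) are out of
  scope; SAEM/importance-sampling estimators are not provided.
- The Laplace approximation can bias variance components at very sparse
  designs (1 observation/subject); recovery tolerances reflect this.
- Empirical Bayes estimates are heavily shrunk at this cohort's small
  BSV (ω² = 0.0188): truth–EBE correlation is ≈0.6 at 3 obs/subject and
  only exceeds 0.7 with richer sampling.
- Steady-state/ADDL dose-expansion codes are not parsed; regimens are
  explicit rows. Covariates are treated as constant within subject for
  estimation (baseline values), although the I/O layer carries forward
  per-row values.
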