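# Methods

## The problem

Drug disposition in livestock varies between animals; how much of that
variation is heritable determines whether drug-metabolism profiles can
be selected on, and whether swine can serve as a genetic model for human
pharmacokinetics. The design studied here is a half-sib resource
population: 198 crossbred nursery pigs by 20 purebred sires of four
breeds (Duroc, Hampshire, Landrace, Yorkshire), housed in nine batches,
each pig dosed intravenously with either fenbendazole (FBZ, 1 mg/kg) or
flunixin meglumine (FLU, 3 mg/kg) and bled at 10 time points over 48 h
(0, 0.5, 1, 2, 3, 4, 6, 12, 24, 48 h for FBZ; 8 h replaces 6 h for
FLU). Parent drug and one metabolite (oxfendazole; 5-hydroxy flunixin)
are quantified per draw. Because half-sibs share a quarter of their
additive genetic effects, the between-sire variance identifies
$\sigma^2_a = 4\,\sigma^2_{sire}$.

Heritability is estimated two ways:

1. **Scalar sire model per PK parameter.** Non-compartmental analysis
   (NCA) reduces each profile to $T_{1/2}$, $Cl$, $AUC_{0\to\infty}$,
   $MRT$, $Vd_{ss}$ (parent) or $AUC_{0\to\infty}$, $C_{max}$,
   $T_{max}$ (metabolite). Each parameter $Y$ is fitted by REML under

   $$Y_{ijklm} = \mu + sex_i + breed_j + batch_k + sire_l + e_{ijklm}/w_{ijklm},$$

   with random batch and sire intercepts and residuals weighted by the
   per-animal terminal-fit $R^2$ (clipped to $[0.01, 1]$).

2. **Random regression over concentration-time data.** Concentrations at
   post-dose hours are modelled with a fixed orthogonal Legendre
   population curve (order $n_f$ = 6 for FBZ, 7 for FLU), fixed sex and
   breed, a random batch intercept and a random sire Legendre regression
   of order $n_r$ (intercept-only everywhere except the FBZ metabolite,
   which carries intercept + slope), residual variance heterogeneous by
   hour, and — for FLU — AR1 serial correlation within animal. The sire
   variance at hour $t$ is the quadratic form
   $\sigma^2_{sire,t} = \mathbf{t}_t S \mathbf{t}_t'$ with
   $\mathbf{t}_t$ the basis row at $t$, and

   $$h^2_t = \frac{4\,\sigma^2_{sire,t}}
     {\sigma^2_{sire,t} + \sigma^2_{batch} + \sigma^2_{e,t}}.$$

The heritability denominator keeps the *sire* variance once (not
$\sigma^2_a$), following the reporting convention of the original
analysis of this design. That convention can exceed 1 when the sire
variance is large; estimates carry an `exceeds_one` flag, and the
variant $4\sigma^2_{sire}/(\sigma^2_{sire}+\sigma^2_e)$ is available via
`denominator="no_batch"`.

## REML engine

The marginal model is $y = X\beta + Z_b u_b + Z_s u_s + e$,
$V = \sigma^2_b Z_bZ_b' + Z_s (I \otimes S) Z_s' + R$, with the
restricted likelihood
$\log L_R = -\tfrac12[\log|V| + \log|X'V^{-1}X| + y'Py]$ (constant
dropped). Rather than factorizing $V$ ($n \approx 1800$ for a
random-regression fit), the likelihood is evaluated through the
mixed-model equations: $\log|V| + \log|X'V^{-1}X| =
\log|R| + \log|G| + \log|C|$ with $C$ the MME coefficient matrix, and
$y'Py = y'R^{-1}y - \hat b' W'R^{-1}y$. Because $R$ is diagonal
(weighted and heterogeneous-by-hour structures) or Markov-banded within
animal (AR1), all data enter through cross-product matrices that are
precomputed once per design; one likelihood evaluation costs
$O((p+q)^2)$ and the engine supports the simulation studies (hundreds
of fits) in seconds. A dense-matrix evaluation of the same formula is
kept in the test suite as an independent oracle and agrees to $10^{-8}$
on small instances for all three residual structures.

For the AR1 structure the within-animal inverse uses the first-order
Markov property: for ordered sampling positions with consecutive-pair
correlations $r_k = \rho^{l_k}$ ($l_k$ the position lag, so a missing
draw widens the gap), the precision matrix is tridiagonal with
$\log|C_{corr}| = \sum_k \log(1-r_k^2)$. AR1 is indexed by sampling
position, not elapsed hours; the spacing of late draws (12, 24, 48 h)
therefore does not collapse their correlation.

### Parameterization and optimization

Variance parameters are optimized unconstrained: $\log\sigma^2$ for
variances, log-Cholesky for $S$ (keeping it positive semidefinite),
Fisher-z for $\rho$. The response is internally standardized to unit
variance (components are rescaled exactly afterwards), so the box
bounds $|\log\sigma^2| \le 18$ are scale-free; a variance driven to the
lower bound is a boundary ("zero") estimate. Optimization is L-BFGS-B
with 3-point finite-difference gradients followed by a Nelder-Mead
polish (`xatol` 1e-10); on balanced one-way designs the fitted sire
variance reproduces the ANOVA closed form to 1e-6. Small
random-regression problems can be multimodal in the log-Cholesky
parameterization; `fit_reml(multi_start=k)` adds $k$ perturbed
restarts, and the study driver uses the default single start on the
full-size designs where the likelihood is well-behaved. Singular or
non-finite points return a large penalty and are logged.

Standard errors: the covariance of the variance parameters is the
inverse of a central finite-difference Hessian on the unconstrained
scale, mapped to the natural scale by the transform Jacobian;
heritability SEs propagate that covariance through the $h^2$ map by a
finite-difference delta method. The parametric bootstrap
(`bootstrap_heritability`, refits warm-started at the fitted
components) is the cross-check; on a seeded synthetic fit the two agree
within 25% per hour. Near a variance boundary the Hessian flattens and
delta SEs become unreliable — estimates there should be read with the
`contains_zero` flag rather than the SE.

Model choice between sire-term orders uses a REML likelihood-ratio test
(valid because the fixed part is unchanged); for variance components on
the boundary the $\tfrac12\chi^2_{df-1} + \tfrac12\chi^2_{df}$ mixture
is applied, which keeps the null rejection rate at or below nominal
(calibration is part of the test suite).

## NCA conventions

Linear trapezoidal AUC/AUMC with exponential tail
($C_{last}/\lambda_z$; $C_{last}t_{last}/\lambda_z +
C_{last}/\lambda_z^2$); a linear-up/log-down variant sits behind
`method="linuplogdown"` since commercial NCA software differs by
configuration. The terminal slope is chosen by best adjusted $R^2$ over
suffixes of at least 3 positive post-dose observations; an interior
(rise-then-fall) peak is excluded from every candidate set, while a
profile declining monotonically from the first quantified sample (IV
parent) admits that sample. Ties prefer more points. Profiles without
an estimable terminal phase are logged and excluded from the weighted
fits. The weight handed to the mixed model is the terminal-fit $R^2$ —
which per-animal diagnostic the original software exported is not
documented, so this is a configurable choice.

## What the generator emulates — and what it does not

`synthpop` reproduces the design: sires nested in breed (5/4/6/5),
progeny counts in 4–24 (mean 9.9), batch sizes (7, 12, 15, 20, 29, 29,
27, 28, 31) and per-batch body-weight distributions, balanced drug
assignment within batch x breed x sex blocks, and sires spread across
batches (partial sire/batch confounding). One drug per animal is
simulated; the crossover used in the first four batches of the real
design is not (carryover was reported negligible).

The forward model is multiplicative: sire, batch and animal deviations
act on two log-scale disposition parameters (`log_scale`, the curve
amplitude, i.e. $-\log Cl$; `log_rate`, the rate constants), guaranteeing
positive concentrations. Parent curves are biexponential IV-bolus
disposition; metabolites are marginal rise-then-fall curves (difference
of exponentials) sharing the animal's deviations rather than a coupled
ODE system — sufficient because the statistical models treat compounds
separately. Default population curves are calibrated so NCA means land
near the observed study means (FLU parent $Cl \approx 0.12$ L/h/kg,
$T_{1/2} \approx 6.6$ h; FBZ parent $T_{1/2} \approx 15$ h; FBZ
metabolite peak $\approx 3.5$ h). The FLU metabolite peaks near 0.5 h as
observed; its printed AUC and $C_{max}$ cannot both be honoured while
keeping the curve quantifiable to 24 h (their ratio forces a 4 h mean
residence), so the default favours $C_{max}$ and a terminal half-life
of ~6 h.

Default variance components on `log_scale`: sire 0.01, batch 0.02,
permanent animal 0.05, plus 28% lognormal measurement noise (serially
AR1 with $\rho = 0.4$ for FLU) and a 0.005 µg/mL limit of
quantification below which values are recorded missing. The measurement
CV of the real assay is unpublished; it is the one free calibration
knob. The permanent animal deviation is kept deliberately modest: the
longitudinal analysis model (like the original) has no
permanent-environment term, so whatever animal-level variance the
generator creates is partly absorbed upward into the sire variance.
This is a faithful property of the design, not a bug — it is the
likely reason across-time metabolite heritabilities exceed their
PK-parameter counterparts — but it means passing recovery tests on
generator data say nothing about permanent-environment bias in real
data. Recovery tests therefore simulate directly under the analysis
model (`simulate_response`, `simulate_sire_trait`), where truth and
model coincide.

### Response scale

Whether the original analysis modelled raw or transformed
concentrations is not documented. This package defaults to
log-concentration for the random-regression study
(`StudyConfig.log_response_rr`): under the multiplicative generative
model the sire effect is then exactly a constant intercept deviation,
matching the intercept-only sire term. On the raw scale a constant sire
variance is bounded by the smallest per-hour total variance — for a
drug spanning two decades of concentration that pins
$\sigma^2_{sire}$ near zero regardless of the true signal. Raw-scale
analysis remains available (`log_response_rr=False`).

## Numerical and reporting conventions

* "Order" = highest Legendre degree ($n_f = 6$ gives 7 coefficients);
  hours map to $[-1, 1]$ linearly from the first post-dose sample to
  the last (log-hour mapping available).
* Reference levels are alphabetical (castrated male, Duroc); factors
  with one observed level drop out.
* Pre-dose (t = 0) records and below-LOQ values are excluded
  observation-wise; unbalanced designs are native to the likelihood.
* Reports round to 2 decimals for PK-level summaries and 3 for the
  time table; every row carries its variance components so the
  heritability is recomputable from the row alone.
* The published across-time table for FLU contains a 16 h row although
  the stated schedule has no 16 h draw; the table is reproduced as
  printed and the discrepancy is surfaced here rather than resolved.
  The FBZ metabolite column of that table was published without SEs;
  this package produces SEs for its own fits regardless.
* Out-of-bounds estimates are never suppressed: everything is reported
  with `exceeds_one` / `contains_zero` flags (the original withheld one
  out-of-bounds $T_{max}$ estimate by an undefined criterion).

## Problem sizes in the simulation studies

The packaged experiments use sizes at which Monte-Carlo error is small
relative to the tolerances while fits stay fast: heritability recovery
at 100 sires x 10 progeny (20 replicates per true $h^2$), boundary
behaviour at 200 sires x 10, LRT null calibration over 200 replicates
of 25 sires x 8, and bootstrap/delta SE comparison on 25 sires x 6 x 5
hours with 200 resamples. The cross-product formulation makes each
scalar fit a few hundred milliseconds, so these are minutes, not hours.

## Known limitations

* Sires are treated as unrelated (pedigree relationships among them
  were reported near zero); no genomic relationship matrix.
* No maternal or litter effects, no dominance; the sire model scales
  only additive variance.
* The delta-method SE of $h^2_t$ ignores uncertainty in choosing
  $n_r$; the LRT chooses the order, then SEs condition on it.
* The metabolite simulation is marginal, so parent-metabolite genetic
  correlations are degenerate (shared deviations) and are not a target
  of inference (the analysis never estimates cross-compound
  correlations).
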