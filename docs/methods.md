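# Methods

## Structural model

Both drugs follow a mammillary two-compartment model with zero-order
(constant-rate infusion) input into and first-order elimination from the
central compartment.  With micro rate constants k10 = CL/Vc, k12 = CLd/Vc,
k21 = CLd/Vp, the disposition eigenvalues λ1 ≥ λ2 solve
λ² − (k10+k12+k21)λ + k10·k21 = 0 and give the alpha/beta half-lives
ln 2/λ.  Concentrations, cumulative AUC and urinary excretion
(CL_R × AUC over a collection interval) are evaluated analytically per dose
and superposed; the ODE system appears only as a test oracle.  Units are
fixed: mg, L, h, mg/L (μg/ml and mg/L are the same number).

Numerical choices in the kinetic core:

- The infusion solution is written with the scaled forms
  φ1(x) = (1−e^(−x))/x and φ2(x) = (x−1+e^(−x))/x², series-expanded for
  |x| < 1e-4 (1e-3), so the one-compartment limit CLd → 0 (a zero
  eigenvalue) and early times are exact to machine precision.
- Near-repeated eigenvalues are handled by symmetrically widening the pair
  to a minimum relative separation of 1e-7 about its mean.  This evaluates
  the repeated-root limit with O(sep²) ≈ 1e-10 relative error — below every
  oracle tolerance used — with a single code path.
- Cmax over a dosing interval is located on a 0.05-h grid (infusion
  start/end knots always included) and polished by bounded scalar
  optimization.

## Covariate model

eGFR uses the 4-variable IDMS-traceable MDRD equation (coefficient 175;
the 186 variant is selectable), with serum creatinine floored at
0.5 mg/dl.  BSA is DuBois & DuBois; BMI is weight/height².  Renal
clearance rises with eGFR as a sigmoidal Emax (Hill) curve with a nonrenal
intercept; linear and power alternatives exist for base-model comparison.

Reference covariate values normalizing the effects are the pooled study
medians — weight 75 kg, age 53 y, height 168 cm, BSA 1.84 m² — the
standard pharmacometric convention when normalization constants are not
part of the parameter table.  The meropenem age and weight factors multiply
total clearance (renal and nonrenal jointly), so the renal fraction of
clearance is invariant to body size and age; the renal-impairment shift
(eGFR ≤ 30) applies to CL_NR only.  Vaborbactam phase shifts reference the
phase 3 (infected) population.  The bundled vaborbactam file carries the
parameter-table values (phase shift on CL 0.517, on Vp 1.28); the
alternatively reported pair (0.264 / 1.78) is available through theta
overrides but is not the default.

Covariates are taken at baseline (each subject's first record).  A
time-varying creatinine series can be converted to an eGFR series with
`mdrd_egfr`, but the estimation engine does not re-derive parameters at
covariate change points: the synthetic studies draw a single creatinine per
subject, and piecewise-constant parameter trajectories would preclude the
closed-form multi-dose superposition the engine is built on.  This is a
known limitation relative to a fully time-varying analysis.

## Population model

Interindividual variability is log-normal on {CL, Vc, CLd, Vp} (the eta on
CL scales CL_R and CL_NR jointly); IIV magnitudes are reported as
%CV = 100·√(exp(ω²)−1).  Residual error is combined
additive-plus-proportional, y = f·(1+ε_p)+ε_a, with separate variance
pairs for plasma and urine; bundled residual magnitudes are interpreted as
variances (a `residual_scale: sd` switch reinterprets them).  Off-diagonal
omega elements default to zero for simulation; estimation can free a full
covariance matrix through a log-Cholesky parameterization.

A `drug: plain` model kind (constant typical values, no built-in covariate
equations, optional extra effects) is the substrate for planted-effect
selection experiments and censoring toys.

## Estimation

The marginal likelihood of each subject is approximated by the Laplace
method at the posterior mode of eta, with the residual variance evaluated
at the eta-dependent prediction (the "interaction" of FOCE-I retained).
The reported objective function value (OFV) is −2 Σ log L including all 2π
constants, so only OFV differences are meaningful across implementations.
BLQ plasma records enter by the Beal M3 construction as left-censored
normal probabilities Φ((LLOQ−pred)/sd).  No claim of numerical equivalence
with any specific FOCE-I implementation is made; on toy subjects the
Laplace OFV sits within 0.1 units of 21-node adaptive Gauss-Hermite
quadrature (the bundled oracle `marginal_loglik_agh`).

Numerics: the inner (posterior-mode) problem advances all subjects
simultaneously — batched finite-difference gradients/Hessians (step 1e-4 on
the log scale), ridged Newton steps capped at 2.0 log units, NaN-aware
backtracking, and a steepest-ascent rescue when indefinite curvature far
from the mode rejects the Newton direction.  The outer problem optimizes
transformed parameters (log for positive thetas and variances, log1p for
proportional shifts bounded below by −1, identity for power coefficients)
with L-BFGS-B, finite-difference step 1e-5, warm-starting each inner solve
from the previous modes.  Standard errors come from a central
finite-difference Hessian of the OFV at the optimum (covariance
2·H⁻¹, delta method back to the natural scale).  Eta shrinkage is
100·(1 − SD(eta)/ω).  A weighted-residual screen (|IWRES| > 6) reports
aberrant records for review and never deletes anything.

## Synthetic studies

The generator emulates the four source designs: a phase 1
multiple-dose study with rich sampling and urine collection on the first
and a steady-state day (1 g / 2 g arms, 3-h infusions q8h), a phase 1
renal study (single 1-g dose, rich plasma + urine, subjects stratified
across normal/mild/moderate/severe/ESRD eGFR bands), and two phase 3
studies (2 g q8h, sparse sampling — two day-1 samples after the end of
infusion, day 3, and the last treatment day — with protocol-style dose
halving below eGFR 30).  Default rich sampling times are 0, 0.5, 1, 2, 3,
3.25, 3.5, 4, 5, 6, 8 h after the intensive-day dose start; urine is
collected over 0–4, 4–8 and 8–24 h.  Covariate draws are truncated
normal/log-normal around the published per-study medians and ranges; eGFR
is never sampled directly but derived from sampled creatinine through MDRD,
which induces the age–renal-function correlation mechanically.  Urine
volumes are log-normal (median 400 ml per 4-h interval, 40% CV) — no
urine-volume model is published.  The BLQ limit defaults to the assay's
lower calibration bound, 0.02 mg/L.

What the generator does **not** emulate: dropout and adherence, assay
drift, time-varying creatinine within a subject, comparator arms, and the
exact five-cohort randomization of the multiple-dose phase 1 study (dose
arms are exposed as a configurable list instead).  Passing tests therefore
demonstrate internal consistency of the method chain under the stated
statistical assumptions, not agreement with any particular clinical
dataset.

## Covariate selection

Screening associates post hoc deviations (etas) with covariates — Spearman
rank correlation for continuous, rank-biserial location shift for binary —
and is advisory only.  Inclusion requires an OFV drop ≥ 3.85 (α = 0.05,
1 df), one candidate per forward step; backward elimination removes a
relation when its deletion costs < 6.635 units (χ²_{0.99,1}, derived from
the stated α = 0.01).  The audit trail records every evaluated ΔOFV.  On
null data with two candidates the per-pass false-inclusion rate sits in
the liberal 10–35% band expected of the asymptotic cut combined with an
approximate (Laplace) likelihood; this is documented, not tuned.

## Diagnostics

The prediction-corrected VPC bins observations by time after the most
recent dose (quantile bins, default 8; empty bins merge left), rescales
observed and simulated values by (bin-median population prediction)/(own
population prediction), and compares observed 5th/50th/95th percentile
curves with the 90% prediction interval of each percentile over simulated
replicates (default 500) on the identical design.  BLQ rows are excluded
from the percentile curves and reported as a per-bin BLQ fraction.
Under self-simulation the observed curves fall inside their bands in ≈90%
of (percentile, bin) cells, the nominal behaviour of an exchangeable
draw; stratification is left to the caller (simulate per-study tables and
run the VPC per table).

## Exposures

Per-subject Cmax (first dosing interval, [0, tau]), day-1 AUC0-24
(analytic), steady-state AUC0-24 = (24/tau)·dose/CL for subjects with at
least three doses (cross-checked against a 30-dose simulation to <0.5%),
and half-lives from the disposition eigenvalues (exact for this model
class, rather than regression on simulated profiles).  Summaries are
geometric mean with geometric %CV (n−1 variance).  Terminal half-lives
above a 24-h cap are blanked from summaries and listed in an exclusion
report; covariate-vs-exposure review is provided as grouped summary tables
(eGFR band, weight quartile, age decade, sex, race), mirroring a
descriptive, not inferential, treatment.

## Validation problem sizes

The test suite and the acceptance script size their simulations for a
single CPU: oracle comparisons use 10–100 random parameter draws;
parameter recovery simulates 200 rich-sampled subjects per drug and takes
the median over three replicate seeds; the censoring comparison uses 40
subjects × 20 seeds at ~45% BLQ; selection operating characteristics use
100 subjects × 20 seeds per arm; VPC calibration uses 100 subjects, 500
replicates, 20 seeds.  These sizes are choices of the validation design,
reported alongside each result.
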