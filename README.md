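# mvpk — population pharmacokinetics of meropenem and vaborbactam

Meropenem-vaborbactam is a carbapenem/beta-lactamase-inhibitor combination
given as 3-h intravenous infusions every 8 h.  Both drugs are cleared
mainly by the kidneys, so their clearance — and therefore the exposure a
patient receives — depends strongly on renal function.  `mvpk` is a
reusable, tested implementation of the population-pharmacokinetic analysis
behind the approved dosing: two-compartment infusion models whose renal
clearance follows a sigmoidal Emax (Hill) function of eGFR, nonlinear
mixed-effects estimation with censored-likelihood (Beal M3) handling of
below-quantitation-limit samples, stepwise covariate selection,
prediction-corrected visual predictive checks, and secondary exposure
metrics (Cmax, AUC0-24, half-lives).  It is aimed at pharmacometricians who
want a dependency-light, scriptable version of this model family, and it
ships a synthetic-study generator emulating the phase 1 and phase 3 designs
so the whole pipeline runs without any clinical data.

## The model

Drug disposition is a two-compartment model with zero-order (infusion)
input and first-order elimination, parameterized by clearances and volumes
(CL, Vc, CLd, Vp) and solved in closed form.  Total clearance splits into a
nonrenal intercept and a saturating renal part,

    CL_R(eGFR) = CLR_max · eGFR^h / (eGFR50^h + eGFR^h),
    CL = (CL_NR + CL_R(eGFR)) · covariate factors,

with eGFR from the 4-variable MDRD creatinine equation (creatinine floored
at 0.5 mg/dl).  Meropenem carries allometric weight scaling on all
parameters (0.75 / 1.0), a power age effect on CL, and a reduction of
CL_NR below eGFR 30; vaborbactam carries height and study-phase effects on
CL, BSA and phase effects on Vc, and a phase effect on Vp.  Between-subject
variability is log-normal on {CL, Vc, CLd, Vp}; residual error is combined
additive-plus-proportional, separately for plasma and urine.  Subjects'
marginal likelihoods are integrated by the Laplace approximation at the
posterior mode of the random effects (interaction retained), and BLQ
records contribute Φ((LLOQ − pred)/sd).

## Worked example

```python
from mvpk import load_model, simulate_study, study_design, CovariateRecord
from mvpk.model import PopPK

model = load_model("meropenem")           # bundled final parameter set

# typical patient: 58 y, 75 kg, eGFR 100 ml/min/1.73 m^2
cov = CovariateRecord(age=58, weight=75, height=168, egfr=100.0)
p = model.typical(cov)
print(f"CL = {p.CL:.2f} L/h, renal fraction = {p.CL_R / p.CL:.3f}")

# simulate a phase-3-like study and refit the renal-saturation parameters
table = simulate_study(study_design("504", n_subjects=50), model, seed=1)
res = PopPK(table, model, free_theta=["clr_max", "egfr50", "hill"]).fit()
print(res.summary())
```

This prints

```
CL = 9.05 L/h, renal fraction = 0.594
```

— a typical 58-year-old with normal renal function clears meropenem at
about 9 L/h, roughly 59% of it renally — followed by a parameter table
with the re-estimated CLR_max / eGFR50 / Hill values, their interindividual
%CVs and eta shrinkage, and the objective-function value of the fit.
`res.vpc()` and `res.exposures()` produce the visual predictive check and
the per-patient Cmax / AUC0-24 / half-life table.

A command-line pipeline wraps the same steps:

```
mvpk simulate --study 505 --n 50 --seed 1 --out run/
mvpk fit --data run/dataset.csv --out run/
mvpk pipeline --n 50 --seed 1 --out run_all/
```

## Layout

- `mvpk.pkcore` — closed-form two-compartment infusion kinetics (AUC,
  Cmax, half-lives, urinary excretion)
- `mvpk.covariates` — MDRD eGFR, DuBois BSA, BMI, covariate equations
- `mvpk.popmodel` — population model assembly, bundled parameter sets
- `mvpk.synthdata` — synthetic study generator (designs 501/504/505/506)
- `mvpk.estimation` — Laplace/M3 mixed-effects engine, post hoc estimates
- `mvpk.selection` — screening plus stepwise forward/backward selection
- `mvpk.diagnostics` — goodness of fit, prediction-corrected VPC
- `mvpk.exposures` — Cmax, AUC0-24 (day 1, steady state), half-lives
- `mvpk.model` — `PopPK` / `PopPKResults` modelling interface
- `mvpk.cli` — `mvpk` command-line pipeline

See `docs/methods.md` for the modelling assumptions, numerical choices and
known limitations.
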