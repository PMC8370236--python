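# Final meropenem population PK model (bundled definition).
# Units: clearances L/h, volumes L, eGFR ml/min/1.73 m^2.
# residual_scale: "variance" means sigma entries are sigma^2 terms of the
# combined error model  y = f·(1+eps_p) + eps_a ;  set "sd" to reinterpret.
drug: meropenem
theta:
  cl_nr: 3.85        # nonrenal clearance intercept
  clr_max: 6.58      # maximal renal clearance
  egfr50: 40.0       # eGFR at half-maximal renal clearance
  hill: 1.95         # sigmoidicity of the renal function curve
  vc: 17.0           # central volume
  cld: 1.36          # distributional clearance
  vp: 2.32           # peripheral volume
  wt_cl: 0.75        # allometric weight exponent on clearances (fixed)
  wt_vc: 1.00        # allometric weight exponent on Vc (fixed)
  wt_cld: 0.75       # allometric weight exponent on CLd (fixed)
  wt_vp: 1.00        # allometric weight exponent on Vp (fixed)
  age_cl: -0.526     # power coefficient of age on CL
  renal_cl_nr: -0.650  # proportional shift on CL_NR when eGFR <= 30
fixed: [wt_cl, wt_vc, wt_cld, wt_vp]
# interindividual variability, %CV on the log scale, order CL, Vc, CLd, Vp
omega_cv: [44.5, 48.4, 51.7, 37.7]
sigma:
  plasma: [0.0423, 0.0204]   # proportional variance, additive variance (mg/L)^2
  urine: [0.207, 0.0511]
residual_scale: variance
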