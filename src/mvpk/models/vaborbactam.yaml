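# Final vaborbactam population PK model (bundled definition).
# Units: clearances L/h, volumes L, eGFR ml/min/1.73 m^2.
# Phase shifts reference the phase 3 (infected) population; they apply to
# phase 1 subjects.  An alternative reported pair for the phase shifts on CL
# (0.264) and Vp (1.78) can be selected via theta overrides.
drug: vaborbactam
theta:
  cl_nr: 0.157       # nonrenal clearance intercept
  clr_max: 8.86      # maximal renal clearance
  egfr50: 49.7       # eGFR at half-maximal renal clearance
  hill: 2.25         # sigmoidicity of the renal function curve
  vc: 17.1           # central volume
  cld: 2.75          # distributional clearance
  vp: 1.77           # peripheral volume
  ht_cl: 2.24        # power coefficient of height on CL
  phase_cl: 0.517    # proportional shift on CL for phase 1 subjects
  bsa_vc: 1.50       # power coefficient of BSA on Vc
  phase_vc: -0.215   # proportional shift on Vc for phase 1 subjects
  phase_vp: 1.28     # proportional shift on Vp for phase 1 subjects
fixed: []
# interindividual variability, %CV on the log scale, order CL, Vc, CLd, Vp
omega_cv: [45.6, 39.4, 34.5, 23.0]
sigma:
  plasma: [0.0372, 0.0287]   # proportional variance, additive variance (mg/L)^2
  urine: [0.115, 5.46]
residual_scale: variance
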