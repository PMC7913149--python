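# Default study configuration.
#
# PK parameter values below are placeholder defaults chosen to give
# plausible tamoxifen/endoxifen exposure (endoxifen steady-state trough
# ~10 ng/mL at 20 mg once daily in a reference normal metaboliser).
# To reproduce a specific published study, transcribe the source-model
# estimates of that study into this section.

model:
  ka: 0.5          # 1/h, first-order absorption
  tlag: 0.5        # h, absorption lag time
  v_tam: 1200.0    # L, apparent tamoxifen central volume (V/F)
  cl20: 5.3        # L/h, tamoxifen clearance to other metabolites (CL/F)
  cl23: 0.46       # L/h, endoxifen formation clearance (CL/F)
  v_endx: 400.0    # L, apparent endoxifen central volume (V/F)
  cl30: 6.0        # L/h, endoxifen elimination clearance (CL/F)
  theta_as:        # CYP2D6 activity score -> fractional change on cl23
    0.0: -0.75
    0.5: -0.55
    1.0: -0.40
    1.5: -0.15
    2.0: 0.0
  theta_age: -0.2  # power exponent of age on cl20
  theta_wt: 0.75   # power exponent of body weight on cl20
  age_ref: 55.0    # years
  wt_ref: 70.0     # kg
  omega2_cl23: 0.20   # IIV variance on ln CL23
  omega2_cl20: 0.09   # IIV variance on ln CL20
  sigma_prop: 0.20    # SD of log-scale proportional residual error (TDM)

population:
  n: 10000
  phenotype_probs: [0.566, 0.378, 0.056]   # gNM / gIM / gPM
  as_within_gnm: {2.0: 0.8, 1.5: 0.2}
  as_within_gim: {1.0: 0.5, 0.5: 0.5}
  age_mean: 55.0
  age_sd: 12.0
  age_range: [25.0, 90.0]
  weight_median: 70.0
  weight_cv: 0.20
  omega2_cl23: 0.20
  omega2_cl20: 0.09

strategies:
  - {id: conventional, kind: conventional}
  - {id: cyp2d6_guided, kind: cyp2d6_guided}
  - {id: mipd_5.97, kind: mipd, target_trough: 5.97}
  - {id: mipd_5.97_plus10, kind: mipd, target_trough: 5.97, dose_increment: 10.0}
  - {id: mipd_9, kind: mipd, target_trough: 9.0}

adherence:
  nonadherent_fraction: 0.40
  missed_scenarios: [1, 2]
  phase1_weeks: 26
  phase2_weeks: 26

seed: 20210203
target_threshold: 5.97
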