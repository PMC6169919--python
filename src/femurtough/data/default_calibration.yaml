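# Default study calibration for the synthetic generators.
#
# Cell means follow  mean(group, week) = anchor * multiplier[group, week]
#                                        + time_slope * week
# with the Sham/control multiplier fixed at 1.  Per-cell SD = cov * mean.
#
# anchor_source: printed  -> the anchor/multiplier/slope values are the
#   study's published summary numbers.
# anchor_source: assumed  -> no absolute value was published; a plausible
#   murine value was fixed once (see docs/methods.md) and only the
#   published *relative* effects are planted around it.
version: 1

cohort:
  weeks: [0, 4, 8, 12]
  n_per_cell: 15
  outcomes:
    K_inst:
      units: "MPa*sqrt(m)"
      sham_anchor: 5.5          # printed Sham anchor
      cov: 0.14                 # printed
      time_slope: 0.0
      rtx_multiplier: {0: 0.58, 4: 0.63, 8: 0.68, 12: 0.72}   # wk0/wk12 printed; wk4/wk8 interpolated
      anchor_source: printed
    K_init:
      units: "MPa*sqrt(m)"
      sham_anchor: 3.0          # assumed absolute level
      cov: 0.14
      time_slope: 0.0377        # printed common slope, MPa*sqrt(m)/wk
      rtx_multiplier: {0: 0.76, 4: 0.76, 8: 0.76, 12: 0.76}   # wk0 printed -24%, held constant
      anchor_source: assumed
    K_pl:
      units: "MPa*sqrt(m)"
      sham_anchor: 5.0          # assumed absolute level
      cov: 0.14
      time_slope: 0.0
      rtx_multiplier: {0: 0.55, 4: 0.62, 8: 0.70, 12: 0.80}   # wk0 -45% and wk12 -20% printed
      anchor_source: assumed
    fracture_angle:
      units: "deg"
      sham_anchor: 16.0
      cov: 0.28
      time_slope: 0.0
      rtx_multiplier: {0: 1.0, 4: 0.70, 8: 0.67, 12: 0.66}    # -30..-34% wks 4-12 printed
      anchor_source: assumed
    Ct_Ar:
      units: "mm^2"
      sham_anchor: 0.95
      cov: 0.06
      time_slope: 0.0
      rtx_multiplier: {0: 1.0, 4: 0.99, 8: 0.963, 12: 0.95}   # wk12 -5% printed; wk8 -3.7%
      anchor_source: assumed
    Ct_Th:
      units: "mm"
      sham_anchor: 0.23
      cov: 0.05
      time_slope: 0.0
      rtx_multiplier: {0: 1.0, 4: 0.949, 8: 0.945, 12: 0.938} # -5.1..-6.2% wks 4-12 printed
      anchor_source: assumed
    Es_Ar:
      units: "mm^2"
      sham_anchor: 0.80
      cov: 0.08
      time_slope: 0.0
      rtx_multiplier: {0: 1.0, 4: 1.08, 8: 1.10, 12: 1.13}    # +8..+13% wks 4-12 printed
      anchor_source: assumed
    TMD:
      units: "mgHA/cm^3"
      sham_anchor: 1150.0
      cov: 0.025
      time_slope: 0.0
      rtx_multiplier: {0: 1.0, 4: 1.0, 8: 1.0, 12: 1.0}       # no treatment effect printed
      anchor_source: assumed
    pentosidine:
      units: "ugQS/ug collagen"
      sham_anchor: 0.030
      cov: 0.25
      time_slope: 0.0
      rtx_multiplier: {0: 1.0, 4: 1.21, 8: 1.0, 12: 1.0}      # +21% at wk4 printed
      anchor_source: assumed
    nsAGE:
      units: "FU/ug collagen"
      sham_anchor: 120.0
      cov: 0.25
      time_slope: 0.0
      rtx_multiplier: {0: 1.0, 4: 1.30, 8: 1.0, 12: 1.0}      # +30% at wk4 printed
      anchor_source: assumed

paired:
  n_pairs: 15
  correlation: 0.7              # within-animal femur-femur correlation (assumed)
  outcomes:
    K_inst:
      control_anchor: 5.5
      cov: 0.14
      multiplier: 0.71          # printed -29%
      anchor_source: printed
    K_init:
      control_anchor: 3.66      # assumed; Sham wk0 sits 18% below this per the printed contrast
      cov: 0.14
      multiplier: 0.74          # printed -26%
      anchor_source: assumed
    K_pl:
      control_anchor: 5.0
      cov: 0.14
      multiplier: 0.74          # printed -26%
      anchor_source: assumed
    fracture_angle:
      control_anchor: 11.4      # printed contralateral mean
      cov: 0.35                 # printed SD 4.0 deg
      multiplier: 0.99          # printed: no significant difference (11.3 vs 11.4 deg)
      anchor_source: printed

ribosylation:
  days: [0, 3, 7, 14]
  n_per_day: 10
  outcomes:
    K_inst:
      intercept: 5.5
      slope: -0.104             # printed, MPa*sqrt(m)/day
      r2: 0.29                  # printed
    K_init:
      intercept: 3.6
      slope: -0.010             # printed
      r2: 0.017                 # printed
    K_pl:
      intercept: 5.0
      slope: -0.040             # printed
      r2: 0.089                 # printed
    pentosidine:
      intercept: 0.030
      slope: 0.006              # printed, ugQS/ug collagen/day
      r2: 0.52                  # printed
    nsAGE:
      intercept: 120.0
      slope: 2.864              # printed, FU/ug collagen/day
      r2: 0.70                  # printed

bed:
  n_fractions: 4
  dose_per_fraction_gy: 5.0
  alpha_beta_gy: 2.8            # back-derived from the published 55.7 Gy BED
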