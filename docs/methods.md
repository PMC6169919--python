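# Methods

## Scope and model

`femurtough` implements the measurement and analysis chain for fracture
toughness testing of notched rodent femurs in three-point bending, the
accompanying μCT cortical morphometry and matrix biochemistry, and the
longitudinal statistics used to compare irradiated (RTx) and sham-treated
cohorts. A calibrated synthetic-data layer generates every input with
planted ground truth, so the full chain is validated end to end without
animal data.

### Stress-intensity model

The femoral mid-diaphysis is idealized as a thin-walled circular cylinder
(mean radius R_m, wall thickness t) carrying a through-wall circumferential
crack of half angle θ. For a mid-span load P over span S, the bending
moment M = PS/4 produces a nominal bending stress

    σ_b = M / (π R_m² t)

and the stress intensity factor is

    K = F_b(θ, R_m/t) · σ_b · √(π R_m θ).

The geometry factor F_b is the Takahashi-style closed form for a cracked
cylinder in bending,

    F_b = 1 + A_b [4.5967 (θ/π)^1.5 + 2.6422 (θ/π)^4.24],

with the amplitude A_b tabulated against r = R_m/t
(`data/geometry_factor_table.json`, version 1) and linearly interpolated
between tabulated levels. The source fit defines A_b = (0.125r − 0.25)^¼
for 5 ≤ r ≤ 10 and (0.4r − 3.0)^¼ for 10 ≤ r ≤ 20; murine cortical
sections sit at r ≈ 2.5–4, so the table extends the first branch down to
r = 2.5, the same extrapolation used throughout the rodent fracture
literature. Requests outside θ ∈ (0, π) or r ∈ [2.5, 20] raise a range
error naming the window.

**Units.** Inputs are N and mm, so stresses come out in MPa and K in
MPa·√mm; results are converted to the conventional MPa·√m by 10^−1.5.

### Crack kinematics and events

Projected crack extension Δa_proj, measured optically on the bone
surface, maps to the instantaneous half crack angle by arc length at the
mean radius, θ = θ₀ + Δa_proj/R_m. This is the standard convention for
surface-tracked circumferential growth; an outer-surface variant is
available through `half_crack_angle(..., radius_mode="outer")` as a
strategy hook, since the choice is a modelling convention rather than a
measured fact.

Three events define the toughness triplet on the imaging frame clock
(loads at frame times by linear interpolation of the denser load trace):

- **initiation** — first frame with Δa_proj above the detection
  threshold. Default 5 pixels (11 μm at the 2.2 μm/px optical
  resolution), about twice the optical noise floor; configurable.
- **peak** — frame of maximum interpolated load.
- **instability** — last frame before a between-frame load drop
  exceeding 10% of peak load, falling back to the final frame with
  measurable extension. The 10% criterion is unambiguous on a 5 Hz
  frame clock; both the fraction and the fallback are configurable.

Ordering (initiation ≤ peak ≤ instability) is enforced: an instability
candidate before the peak is clamped to the peak, while initiation after
the peak raises, since such a record is not a monotone rise-then-failure
test.

### LEFM validity

The linear-elastic treatment assumes small-scale yielding. The Irwin
plane-strain plastic-zone radius r_p = (K/σ_y)²/(6π) is evaluated at a
cortical yield strength of 160 MPa (plane stress, 1/(2π), by flag) and a
measurement is flagged valid when r_p ≤ t/10. For typical murine
geometry this reproduces the known behaviour that K below ~3 MPa√m is
comfortably valid while peak/instability values are not strictly valid —
they are flagged, never rejected, because group comparisons remain
meaningful.

### Fracture angle

The global fracture angle α is the angle between the notch-root→breakout
line and the transverse plane, α = atan(|Δlong|/|Δtransverse|), so 0°
is a perfectly transverse fracture. Lower α = more transverse pattern.

### Morphometry

Cortical segmentation thresholds the calibrated density grid at
654 mg HA/cm³ (inclusive) and keeps the largest connected component.
Areas: Ct.Ar counts cortical pixels, Tt.Ar counts the hole-filled
periosteal region, Es.Ar = Tt.Ar − Ct.Ar (additivity exact by
construction). Principal second moments come from the eigenvalues of the
2×2 area inertia tensor about the centroid, with the per-pixel 1/12 px⁴
self-moment included. Mean cortical thickness uses the local-thickness
convention: twice the Euclidean distance transform sampled at its ridge
(local maxima along the cortical midline), with a −1 px center-to-center
correction; a radial-ray fallback is provided. The analysis is 2D
per-slice at the notch plane — the section that actually enters the K
computation — with stack inputs averaged. The equivalent-area annulus
(R_o from Tt.Ar, R_i from Es.Ar) feeds the fracture geometry.

### Biochemistry

Pentosidine is read against a linear quinine-sulfate standard curve
(fluorescence is linear in the assay range; inverse prediction refuses
readings beyond 120% of the top standard), nsAGE is raw fluorescence at
plate gain 100 and is comparable only within a plate, and collagen mass
is hydroxyproline / 0.135. Both AGE measures are normalized per μg
collagen; mineral:matrix is μCT bone mineral content over collagen.
Technical triplicates are averaged with a CV > 15% quality flag (the
replicate-acceptance rule is not standardized; 15% is a common assay
default and configurable).

### Statistics battery

Unpaired equal-variance t-tests per time point (Welch by flag), percent
change as [(RTx − Sham)/Sham]·100 on group means, paired t-tests for the
contralateral design, one-way ANOVA with Tukey HSD, OLS regressions, and
Cohen's d with small/medium/large classes at 0.2/0.5/0.8. ANCOVA fits
`outcome ~ treatment * time` and reports the treatment, time and
interaction p-values and full-model R²; the common time slope is
reported from the additive refit, the quantity of interest when the
interaction is retained-but-nonsignificant. No multiple-testing
correction is applied across time points or outcomes, mirroring the
per-comparison convention of the study design this battery reproduces;
treat the p-values accordingly.

## Synthetic-data generators

The generators plant the published summary effects so that the analysis
chain can be checked for *recovery*, not just for crashing:

- **Cohort** (`gen_cohort`): Sham and RTx × weeks 0/4/8/12, n = 15 per
  cell. Cell mean = anchor · multiplier(group, week) + slope · week;
  per-cell SD = COV · mean. Outcome noise is normal — at COV 0.14 the
  negative tail is negligible (≈10⁻¹²) — with a documented lognormal
  alternative deliberately not taken to keep percent-change algebra
  exact. The K_inst anchor (5.5 MPa√m, COV 0.14) and the week-0/−42%
  and week-12/−28% multipliers are published values; week-4/8
  multipliers are interpolated. K_init carries the published common
  time slope 0.0377 MPa√m/wk with a constant −24% treatment offset.
  Anchors without published absolute values (K_init 3.0, K_pl 5.0
  MPa√m, Ct.Ar 0.95 mm², and others marked `anchor_source: assumed` in
  `data/default_calibration.yaml`) were fixed once at values typical
  for 12-week female BALB/cJ femurs; only the published *relative*
  effects around them are asserted anywhere.
- **Paired devitalized design** (`gen_paired_femurs`): per-animal shared
  latent factor giving within-animal correlation 0.7 (not published;
  0.7 is typical for contralateral bone pairs and is a parameter), with
  the treated femur mean scaled by the planted multiplier (−29% for
  K_inst, published).
- **Ribosylation** (`gen_ribosylation`): days 0/3/7/14, n = 10/day;
  outcome = intercept + slope·day + ε with ε chosen from the planted R²
  via σ² = slope²·var(day)·(1−R²)/R², var(day) = 27.5 for the balanced
  design. Published slopes/R²: K_inst −0.104/day (0.29), pentosidine
  0.006/day (0.52), nsAGE 2.864/day (0.70). Note the *sample* R² of a
  refit is biased upward by ≈(1−ρ²)/(n−2) ≈ 0.02 at n = 40; tests
  account for this analytically rather than by recalibration.
- **Bend test** (`gen_bend_test`): inverts the K formula frame by frame
  so the planted R-curve is recovered exactly (the forward model and
  analyzer share the geometry factor by design — the closure test
  checks the kinematics, interpolation and event logic, not the factor
  itself, which is checked against its coefficient table). Event times
  land on the 5 Hz frame clock; the dense load trace is sampled at a
  multiple of the frame rate so frame-time interpolation is exact.
- **Section mask** (`gen_section_mask`): pixel-center rasterization of a
  (possibly elliptical) annulus with constant wall offset; the truth
  sidecar carries closed-form areas, moments and thickness. For
  ellipticity up to ~1.3 the constant-wall approximation holds to well
  under a pixel at 12 μm resolution.
- **BED** (`bed_linear_quadratic`): n·d·(1 + d/(α/β)). The packaged
  protocol (4 × 5 Gy) reproduces the published 55.7 Gy at
  α/β = 2.8 Gy, the value back-derived from that printed BED.

### What the generators do not emulate

Real bend tests have compliance nonlinearity, toe regions, optical
tracking dropouts and non-flat 3D crack fronts; real μCT sections are
not perfect annuli and carry beam-hardening artefacts; plates have batch
effects. Passing recovery tests therefore demonstrates that the
*analysis chain* is correct and calibrated — not that it is robust to
every artefact of real instrumentation, which is out of scope here.

## Numerical choices

- Geometry-factor table interpolation is linear in r; the θ polynomial
  is evaluated exactly. F_b is continuous and ≥ 1 across the grid.
- Half crack angles ≥ π are clipped just below π with a warning.
- Loads at crack frames: linear interpolation in time (imaging at 5 Hz
  vs denser load sampling).
- Thickness: EDT is center-to-center, so the wall spans 2d − 1 pixel
  widths at ridge distance d; exact for odd pixel walls, −1 px worst
  case for even — inside the ±1 px accuracy target.
- Degenerate inputs raise typed errors (`femurtough.errors`): empty
  masks, non-annular topology, zero collagen, non-monotone standards,
  rank-deficient ANCOVA designs, coincident fracture-angle points.

## Problem sizes

Monte-Carlo validation uses 500 replicates per recovery check and 2000
null simulations for type-I calibration, sizes at which Monte-Carlo
standard errors (≈0.1–0.2 percentage points for percent changes) are far
below the planted effects. The large-n calibration-fidelity check uses
n = 10⁴ draws per cell.

## Known limitations

- The geometry-factor coefficients below r = 5 are an extrapolation of
  the published fit, as in the rodent literature; absolute K at very
  thick-walled sections inherits that uncertainty.
- Single-location crack tracking assumes a flat, symmetric crack front.
- Elastic-plastic toughness (J-integral) is out of scope; LEFM flags
  mark where the elastic assumption thins.
- nsAGE fluorescence units are plate-relative; cross-plate comparisons
  require a batch column and are not corrected internally.
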