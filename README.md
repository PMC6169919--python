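# femurtough

Fracture-toughness analysis for notched rodent femurs tested in
three-point bending, with the cortical μCT morphometry, matrix (AGE)
biochemistry and longitudinal statistics that surround such tests in
skeletal radiobiology and bone-quality studies.

The package is aimed at bone biomechanics labs that track crack growth
optically during a bend test and want the full chain — from a raw
load–displacement trace plus crack-extension frames to the toughness
triplet, through cohort-level inference — as tested, scriptable code. A
calibrated synthetic-data layer generates every input with planted
ground truth, so the pipeline is verifiable end to end without animal
data.

## The model

The femoral mid-diaphysis is idealized as a thin-walled cylinder (mean
radius R_m, wall thickness t) with a through-wall circumferential crack
of half angle θ. Surface-tracked crack extension maps to the crack angle
as θ = θ₀ + Δa_proj / R_m, and the stress intensity factor under a
mid-span load P over span S is

    K = F_b(θ, R_m/t) · σ_b · √(π R_m θ),        σ_b = (P S / 4) / (π R_m² t)

with F_b the tabulated geometry factor for a cracked cylinder in
bending. K is evaluated at three events on the imaging frame clock —
crack initiation, peak load, and the onset of unstable growth — giving
the toughness triplet (K_init, K_pl, K_inst) in MPa·√m, each with an
Irwin plastic-zone check of the linear-elastic assumption. See
`docs/methods.md` for conventions, thresholds and limitations.

## Worked example

```python
import femurtough as ft
from femurtough.simulate import gen_bend_test, DEFAULT_NOTCH, DEFAULT_SECTION

record, truth = gen_bend_test(seed=0)          # forward-modelled bend test
result = ft.toughness_triplet(record, DEFAULT_NOTCH, DEFAULT_SECTION)
print(result.summary())
```

```
event        K (MPa*sqrt(m))  theta (rad)    P (N)   LEFM   r_p/t
initiation             3.000       0.6142    14.72     ok   0.075
peak                   5.000       0.7935    19.74     NO   0.207
instability            5.500       1.0516    16.48     NO   0.251
```

The analyzer recovers the planted triplet (3.0 / 5.0 / 5.5 MPa·√m)
exactly, at loads of 15–20 N typical for a mouse femur. The LEFM column
shows the expected pattern: the initiation value (plastic zone ≈ 7% of
the wall) satisfies small-scale yielding, while the larger peak and
instability values are flagged — they remain useful for group
comparisons but are not strictly valid LEFM measurements.

Cohort-level inference on a simulated study (two groups, n = 15/group):

```python
from femurtough.simulate import gen_cohort
table, _ = gen_cohort(seed=1, outcomes=["K_inst"], weeks=[0, 12])
print(ft.timepoint_tests(table, "K_inst")[["mean_Sham", "mean_RTx", "p", "percent_change"]])
```

```
      mean_Sham  mean_RTx    p  percent_change
week
0        5.5741    3.0880  0.0        -44.6005
12       5.4522    3.9593  0.0        -27.3817
```

i.e. an immediate ~−42% drop in instability toughness in the treated
group that persists (~−28%) at 12 weeks, recovered here from a single
simulated cohort within sampling noise of the planted effects.

A CLI mirrors the library for shell use:

```sh
femurtough simulate bendtest --seed 4 --out demo/
femurtough toughness --record demo/record.csv --frames demo/frames.csv --geometry demo/geometry.json
femurtough run-study --seed 7 --out study_out/
```

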