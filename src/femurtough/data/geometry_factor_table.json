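{
  "version": 1,
  "description": "Geometry factor F_b for a through-wall circumferential crack in a cylinder under bending: F_b = 1 + A_b * (c1*(theta/pi)^e1 + c2*(theta/pi)^e2), with the amplitude A_b tabulated against the radius-to-thickness ratio r = R_m/t and linearly interpolated between levels. Levels at r <= 4 extend the thin-cylinder branch below its nominal 5-20 window to cover murine cortical geometry.",
  "angle_coefficients": [4.5967, 2.6422],
  "angle_exponents": [1.5, 4.24],
  "ab_table": [
    [2.5, 0.500000],
    [3.0, 0.594604],
    [3.5, 0.658037],
    [4.0, 0.707107],
    [5.0, 0.782542],
    [6.0, 0.840896],
    [7.0, 0.889140],
    [8.0, 0.930605],
    [9.0, 0.967168],
    [10.0, 1.000000],
    [12.0, 1.158292],
    [15.0, 1.316074],
    [20.0, 1.495349]
  ]
}
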