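"""Synthetic-data generators with planted, recoverable ground truth.

Every input the pipeline consumes can be generated here: cohort tables
with planted group×time effects, paired (contralateral-control) femur
designs, ribosylation dose–response series, forward-modelled bend-test
records whose toughness triplet is known exactly, and rasterized annular
cross sections with closed-form morphometry.  The shipped default
calibration plants the study's published summary effects (Sham K_inst
5.5 MPa√m at COV 0.14, −42%/−28% treatment effects at weeks 0/12, the
ribosylation slopes, ...) so the whole analysis chain can be exercised
and validated without any animal data.

All generators are deterministic given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import CalibrationError, GeometryError, InputError
from .fracture import (
    BendTestRecord,
    geometry_factor,
    half_crack_angle,
    stress_intensity,
)
from .geometry import CrossSection, NotchGeometry
from .morphometry import SectionImage


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

class StudyCalibration:
    """Planted means, dispersions and effects for the study design.

    Wraps the calibration mapping (see ``data/default_calibration.yaml``)
    and validates its invariants: positive COVs and multipliers, planted
    R² strictly inside (0, 1).
    """

    def __init__(self, raw: dict):
        self.raw = raw
        self._validate()

    @classmethod
    def default(cls) -> "StudyCalibration":
        text = (
            resources.files("femurtough.data")
            .joinpath("default_calibration.yaml")
            .read_text()
        )
        return cls(yaml.safe_load(text))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyCalibration":
        return cls(yaml.safe_load(Path(path).read_text()))

    def _validate(self) -> None:
        for name, spec in self.raw.get("cohort", {}).get("outcomes", {}).items():
            if not spec["cov"] > 0:
                raise CalibrationError(f"{name}: COV must be > 0")
            if any(m <= 0 for m in spec["rtx_multiplier"].values()):
                raise CalibrationError(f"{name}: multipliers must be > 0")
        for name, spec in self.raw.get("paired", {}).get("outcomes", {}).items():
            if not (spec["cov"] > 0 and spec["multiplier"] > 0):
                raise CalibrationError(f"paired {name}: COV and multiplier must be > 0")
        rho = self.raw.get("paired", {}).get("correlation", 0.7)
        if not 0.0 <= rho <= 1.0:
            raise CalibrationError("paired correlation must lie in [0, 1]")
        for name, spec in self.raw.get("ribosylation", {}).get("outcomes", {}).items():
            if not 0.0 < spec["r2"] < 1.0:
                raise CalibrationError(f"ribosylation {name}: planted R2 must be in (0,1)")

    @property
    def cohort(self) -> dict:
        return self.raw["cohort"]

    @property
    def paired(self) -> dict:
        return self.raw["paired"]

    @property
    def ribosylation(self) -> dict:
        return self.raw["ribosylation"]

    @property
    def bed(self) -> dict:
        return self.raw["bed"]


def _multipliers(spec: dict) -> dict[float, float]:
    return {float(k): float(v) for k, v in spec["rtx_multiplier"].items()}


def _cell_mean(spec: dict, group: str, week: float) -> float:
    mult = 1.0 if group == "Sham" else _multipliers(spec)[float(week)]
    return float(spec["sham_anchor"]) * mult + float(spec.get("time_slope", 0.0)) * week


# ---------------------------------------------------------------------------
# cohort generators
# ---------------------------------------------------------------------------

def gen_cohort(
    calibration: StudyCalibration | None = None,
    seed: int = 0,
    outcomes: list[str] | None = None,
    weeks: list[float] | None = None,
    n_per_cell: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate the longitudinal Sham/RTx cohort.

    Draws per-cell normal outcomes with planted mean and COV for the
    default design (two groups × weeks 0/4/8/12, n = 15 per cell).
    Returns the long-format table and a ground-truth sidecar with the
    planted cell means and percent changes.
    """
    calibration = calibration or StudyCalibration.default()
    rng = np.random.default_rng(seed)
    design = calibration.cohort
    weeks = list(weeks) if weeks is not None else list(design["weeks"])
    n = int(n_per_cell or design["n_per_cell"])
    specs = design["outcomes"]
    names = list(outcomes) if outcomes is not None else list(specs)
    unknown = set(names) - set(specs)
    if unknown:
        raise CalibrationError(f"no calibration for outcomes {sorted(unknown)}")

    rows, truth = [], {}
    for name in names:
        spec = specs[name]
        truth[name] = {}
        for week in weeks:
            if float(week) not in _multipliers(spec):
                raise CalibrationError(f"{name}: no multiplier for week {week}")
            cell_truth = {}
            for group in ("Sham", "RTx"):
                mean = _cell_mean(spec, group, week)
                sd = float(spec["cov"]) * abs(mean)
                vals = rng.normal(mean, sd, n)
                cell_truth[group] = mean
                for i, v in enumerate(vals):
                    rows.append(
                        {
                            "specimen": f"{group}-w{week}-{i:02d}",
                            "group": group,
                            "week": week,
                            "outcome": name,
                            "value": float(v),
                        }
                    )
            cell_truth["percent_change"] = (
                (cell_truth["RTx"] - cell_truth["Sham"]) / cell_truth["Sham"] * 100.0
            )
            truth[name][week] = cell_truth
    return pd.DataFrame(rows), truth


def gen_paired_femurs(
    calibration: StudyCalibration | None = None,
    seed: int = 0,
    outcomes: list[str] | None = None,
    n_pairs: int | None = None,
    correlation: float | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate the devitalized paired design (treated vs contralateral).

    Each animal gets a shared latent baseline; the two femurs share a
    fraction ``correlation`` of the outcome variance, and the treated
    femur mean is scaled by the planted multiplier.
    """
    calibration = calibration or StudyCalibration.default()
    rng = np.random.default_rng(seed)
    design = calibration.paired
    rho = float(correlation if correlation is not None else design["correlation"])
    if not 0.0 <= rho <= 1.0:
        raise CalibrationError("correlation must lie in [0, 1]")
    n = int(n_pairs or design["n_pairs"])
    specs = design["outcomes"]
    names = list(outcomes) if outcomes is not None else list(specs)
    unknown = set(names) - set(specs)
    if unknown:
        raise CalibrationError(f"no paired calibration for outcomes {sorted(unknown)}")

    rows, truth = [], {}
    for name in names:
        spec = specs[name]
        anchor, cov, mult = (
            float(spec["control_anchor"]),
            float(spec["cov"]),
            float(spec["multiplier"]),
        )
        z_shared = rng.normal(size=n)
        z_ctrl = rng.normal(size=n)
        z_trt = rng.normal(size=n)
        mix_c = math.sqrt(rho) * z_shared + math.sqrt(1.0 - rho) * z_ctrl
        mix_t = math.sqrt(rho) * z_shared + math.sqrt(1.0 - rho) * z_trt
        ctrl = anchor * (1.0 + cov * mix_c)
        trt = anchor * mult * (1.0 + cov * mix_t)
        truth[name] = {
            "control_mean": anchor,
            "treated_mean": anchor * mult,
            "percent_change": (mult - 1.0) * 100.0,
        }
        for i in range(n):
            rows.append(
                {
                    "specimen": f"A{i:02d}-L",
                    "animal": f"A{i:02d}",
                    "group": "control",
                    "outcome": name,
                    "value": float(ctrl[i]),
                }
            )
            rows.append(
                {
                    "specimen": f"A{i:02d}-R",
                    "animal": f"A{i:02d}",
                    "group": "RTx",
                    "outcome": name,
                    "value": float(trt[i]),
                }
            )
    return pd.DataFrame(rows), truth


def gen_ribosylation(
    calibration: StudyCalibration | None = None,
    seed: int = 0,
    outcomes: list[str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate the ex vivo ribosylation dose–response (days 0/3/7/14).

    Outcomes follow ``intercept + slope*day + e`` with the residual SD
    derived from the planted R² and the day design's variance, so an
    OLS refit recovers both the slope and (in expectation) the R².
    """
    calibration = calibration or StudyCalibration.default()
    rng = np.random.default_rng(seed)
    design = calibration.ribosylation
    days = np.asarray(design["days"], dtype=float)
    n = int(design["n_per_day"])
    specs = design["outcomes"]
    names = list(outcomes) if outcomes is not None else list(specs)
    unknown = set(names) - set(specs)
    if unknown:
        raise CalibrationError(f"no ribosylation calibration for {sorted(unknown)}")

    all_days = np.repeat(days, n)
    var_days = float(np.var(all_days))  # 27.5 for the balanced 0/3/7/14 design
    rows, truth = [], {}
    for name in names:
        spec = specs[name]
        slope, intercept, r2 = float(spec["slope"]), float(spec["intercept"]), float(spec["r2"])
        signal_var = slope**2 * var_days
        resid_sd = math.sqrt(signal_var * (1.0 - r2) / r2) if slope != 0 else float(
            spec.get("resid_sd", 1.0)
        )
        vals = intercept + slope * all_days + rng.normal(0.0, resid_sd, all_days.size)
        truth[name] = {"slope": slope, "intercept": intercept, "r2": r2,
                       "resid_sd": resid_sd}
        for i, (d, v) in enumerate(zip(all_days, vals)):
            rows.append(
                {
                    "specimen": f"R{i:02d}",
                    "group": f"day{int(d)}",
                    "day": float(d),
                    "outcome": name,
                    "value": float(v),
                }
            )
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# bend-test forward model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedRCurve:
    """Ground-truth crack-growth resistance at the three loading events.

    ``delta_a`` and ``k`` hold projected crack extension (mm) and
    toughness (MPa·√m) at initiation, peak load and instability.
    """

    delta_a: tuple[float, float, float] = (0.011, 0.15, 0.35)
    k: tuple[float, float, float] = (3.0, 5.0, 5.5)

    def __post_init__(self) -> None:
        if len(self.delta_a) != 3 or len(self.k) != 3:
            raise InputError("planted R-curve needs exactly three events")
        if any(np.diff(self.delta_a) < 0):
            raise InputError("planted crack extension must be non-decreasing")
        if any(v < 0 for v in self.k):
            raise InputError("planted K values must be non-negative")


#: default equivalent-annulus geometry for a murine femoral mid-diaphysis
DEFAULT_SECTION = CrossSection(outer_radius=0.9, inner_radius=0.65)
DEFAULT_NOTCH = NotchGeometry(initial_half_angle=0.6, notch_depth=0.65)


def gen_bend_test(
    section: CrossSection = DEFAULT_SECTION,
    notch: NotchGeometry = DEFAULT_NOTCH,
    planted: PlantedRCurve | None = None,
    seed: int = 0,
    span: float = 8.0,
    frame_rate_hz: float = 5.0,
    load_rate_hz: float = 100.0,
    event_times_s: tuple[float, float, float] = (4.0, 8.0, 12.0),
    displacement_rate_mm_s: float = 0.1 / 60.0,
    load_noise_sd_n: float = 0.0,
) -> tuple[BendTestRecord, dict]:
    """Forward-model a bend test whose toughness triplet is planted.

    Crack extension grows piecewise-linearly through the planted event
    extensions on the 5 Hz frame clock; at each cracked frame the load is
    solved so that the stress intensity equals the planted R-curve
    (linearly interpolated in time between events).  Before initiation
    the load ramps linearly; after instability the load collapses so the
    between-frame drop criterion fires.  The dense load trace is the
    frame profile resampled at ``load_rate_hz`` (frame times lie on the
    dense clock, so the record round-trips exactly), displacement is a
    monotone constant-rate proxy, and optional Gaussian noise can be
    added to the dense load samples.

    Returns the record plus a ground-truth sidecar with the planted K
    values and event frame indices.
    """
    planted = planted or PlantedRCurve()
    rng = np.random.default_rng(seed)
    t_init, t_peak, t_inst = event_times_s
    if not 0.0 < t_init <= t_peak <= t_inst:
        raise InputError("event times must satisfy 0 < init <= peak <= instability")
    if load_rate_hz % frame_rate_hz != 0:
        raise InputError("load sampling rate must be a multiple of the frame rate")
    dt = 1.0 / frame_rate_hz
    n_tail = 2  # post-instability frames carrying the catastrophic drop
    frame_time = np.arange(0.0, t_inst + (n_tail + 0.5) * dt, dt)
    idx_init = int(round(t_init / dt))
    idx_peak = int(round(t_peak / dt))
    idx_inst = int(round(t_inst / dt))
    if not np.isclose(frame_time[idx_init], t_init):
        raise InputError("event times must land on the frame clock")

    # piecewise-linear crack extension through the planted event values
    da = np.zeros_like(frame_time)
    ev_t = [t_init, t_peak, t_inst]
    da[idx_init:] = np.interp(frame_time[idx_init:], ev_t, list(planted.delta_a))
    da[idx_inst + 1:] = planted.delta_a[2] + 0.5  # catastrophic jump

    # planted K interpolated in time between events
    k_profile = np.interp(frame_time, ev_t, list(planted.k))

    ratio = section.radius_thickness_ratio
    load = np.zeros_like(frame_time)
    for i in range(idx_init, idx_inst + 1):
        theta = half_crack_angle(notch, float(da[i]), section)
        fb = geometry_factor(theta, ratio)
        k_per_newton = stress_intensity(1.0, span, section, theta, fb)
        load[i] = k_profile[i] / k_per_newton
    # pre-initiation ramp up to the initiation load
    load[: idx_init + 1] = np.linspace(0.0, load[idx_init], idx_init + 1)
    # post-instability collapse (> 10% of peak between frames)
    load[idx_inst + 1:] = 0.02 * load[idx_peak]

    if int(np.argmax(load)) != idx_peak:
        raise GeometryError(
            "planted R-curve does not produce its load peak at the planted "
            "peak frame; adjust the planted profile"
        )

    time = np.arange(0.0, frame_time[-1] + 0.5 / load_rate_hz, 1.0 / load_rate_hz)
    dense_load = np.interp(time, frame_time, load)
    if load_noise_sd_n > 0:
        dense_load = np.clip(dense_load + rng.normal(0.0, load_noise_sd_n, time.size), 0.0, None)
    displacement = displacement_rate_mm_s * time

    record = BendTestRecord(
        time=time,
        load=dense_load,
        displacement=displacement,
        frame_time=frame_time,
        delta_a=da,
        span=span,
    )
    truth = {
        "initiation_index": idx_init,
        "peak_index": idx_peak,
        "instability_index": idx_inst,
        "K_init": planted.k[0],
        "K_pl": planted.k[1],
        "K_inst": planted.k[2],
    }
    return record, truth


# ---------------------------------------------------------------------------
# section rasterizer
# ---------------------------------------------------------------------------

def gen_section_mask(
    outer_radius_mm: float = 0.9,
    inner_radius_mm: float = 0.65,
    ellipticity: float = 1.0,
    pixel_size_um: float = 12.0,
    density: float = 1200.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    padding_px: int = 4,
) -> tuple[SectionImage, dict]:
    """Rasterize an (elliptical) annular cortex at a planted density.

    The outer boundary is an ellipse with semi-axes
    ``(ellipticity * R_o, R_o)``; the inner boundary is offset inward by
    the constant wall thickness ``R_o − R_i`` on both axes.  Optional
    Gaussian speckle is added to cortical pixels only.  The truth
    sidecar carries closed-form areas, principal moments and wall
    thickness for use as an oracle.
    """
    if not outer_radius_mm > inner_radius_mm > 0:
        raise InputError("require outer radius > inner radius > 0")
    if ellipticity < 1.0:
        raise InputError("ellipticity is the major/minor axis ratio, >= 1")
    rng = np.random.default_rng(seed)
    px = pixel_size_um * 1e-3
    wall = outer_radius_mm - inner_radius_mm
    a_out, b_out = ellipticity * outer_radius_mm, outer_radius_mm
    a_in, b_in = a_out - wall, b_out - wall
    if a_in <= 0 or b_in <= 0:
        raise InputError("wall thickness swallows the endosteal cavity")

    half_x = a_out + padding_px * px
    half_y = b_out + padding_px * px
    nx = int(math.ceil(2 * half_x / px))
    ny = int(math.ceil(2 * half_y / px))
    # pixel-center coordinates, origin at the grid corner
    x = (np.arange(nx) + 0.5) * px - half_x
    y = (np.arange(ny) + 0.5) * px - half_y
    xx, yy = np.meshgrid(x, y)
    outer = (xx / a_out) ** 2 + (yy / b_out) ** 2 <= 1.0
    inner = (xx / a_in) ** 2 + (yy / b_in) ** 2 <= 1.0
    mask = outer & ~inner

    grid = np.zeros((ny, nx))
    grid[mask] = density
    if noise_sd > 0:
        grid[mask] = np.clip(grid[mask] + rng.normal(0.0, noise_sd, int(mask.sum())), 0.0, None)

    i_x = math.pi / 4.0 * (a_out * b_out**3 - a_in * b_in**3)
    i_y = math.pi / 4.0 * (a_out**3 * b_out - a_in**3 * b_in)
    truth = {
        "mask": mask,
        "Tt_Ar": math.pi * a_out * b_out,
        "Es_Ar": math.pi * a_in * b_in,
        "Ct_Ar": math.pi * (a_out * b_out - a_in * b_in),
        "Ct_Th": wall,
        "I_min": min(i_x, i_y),
        "I_max": max(i_x, i_y),
        "TMD": density,
    }
    return SectionImage(density=grid, pixel_size_um=pixel_size_um), truth


# ---------------------------------------------------------------------------
# radiobiology
# ---------------------------------------------------------------------------

def bed_linear_quadratic(
    n_fractions: int, dose_per_fraction: float, alpha_beta: float
) -> float:
    """Biologically effective dose of a fractionated protocol, in Gy.

    Linear-quadratic model: ``BED = n · d · (1 + d / (α/β))``.  As the
    dose per fraction vanishes the BED tends to the physical dose.
    """
    if alpha_beta <= 0:
        raise InputError("alpha/beta must be positive")
    if n_fractions <= 0 or dose_per_fraction <= 0:
        raise InputError("fraction count and dose per fraction must be positive")
    return n_fractions * dose_per_fraction * (1.0 + dose_per_fraction / alpha_beta)
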