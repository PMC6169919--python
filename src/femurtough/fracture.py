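"""Fracture toughness of a notched femur in three-point bending.

The mid-diaphysis is idealized as a thin-walled cylinder carrying a
through-wall circumferential crack.  Crack extension measured on the
bone surface is mapped to an instantaneous half crack angle, a tabulated
geometry factor converts the bending stress into a stress intensity
factor, and three loading events — crack initiation, peak load and the
onset of unstable growth — yield the toughness triplet
``(K_init, K_pl, K_inst)``.

Working units are N and mm throughout (so stresses come out in MPa);
stress intensities are reported in MPa·√m.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Literal, Sequence

import numpy as np

from .errors import EventDetectionError, GeometryError, InputError, RangeError
from .geometry import CrossSection, NotchGeometry

#: multiply MPa·√mm by this to get MPa·√m  (√mm = 10^-1.5 √m)
MPA_SQRT_MM_TO_MPA_SQRT_M = 10.0 ** -1.5

#: cortical bone yield strength used for plastic-zone estimates, MPa
DEFAULT_YIELD_STRENGTH_MPA = 160.0

#: optical resolution of the crack-monitoring camera, μm per pixel
DEFAULT_PIXEL_SIZE_UM = 2.2

#: default three-point-bend support span, mm
DEFAULT_SPAN_MM = 8.0


# ---------------------------------------------------------------------------
# records and results
# ---------------------------------------------------------------------------

@dataclass
class BendTestRecord:
    """Synchronized load–displacement trace plus crack-extension series.

    The load frame samples ``(time, load, displacement)`` densely; the
    crack camera samples projected crack extension ``delta_a`` on its own
    (sparser, e.g. 5 Hz) frame clock ``frame_time``.  Loads at crack
    frames are obtained by linear interpolation in time.
    """

    time: np.ndarray                # s, strictly increasing
    load: np.ndarray                # N
    displacement: np.ndarray        # mm
    frame_time: np.ndarray          # s
    delta_a: np.ndarray             # mm, projected crack extension, non-decreasing
    span: float = DEFAULT_SPAN_MM   # mm
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.load = np.asarray(self.load, dtype=float)
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.frame_time = np.asarray(self.frame_time, dtype=float)
        self.delta_a = np.asarray(self.delta_a, dtype=float)
        if self.time.ndim != 1 or self.time.size < 2:
            raise InputError("need at least two load samples")
        if not (self.time.size == self.load.size == self.displacement.size):
            raise InputError("time, load and displacement must have equal length")
        if self.frame_time.size != self.delta_a.size or self.frame_time.size < 1:
            raise InputError("frame_time and delta_a must be non-empty and equal length")
        if np.any(np.diff(self.time) <= 0):
            raise InputError("time must be strictly increasing")
        if np.any(np.diff(self.frame_time) <= 0):
            raise InputError("frame_time must be strictly increasing")
        if np.any(~np.isfinite(self.load)) or np.any(self.load < 0):
            raise InputError("loads must be finite and non-negative")
        if np.any(np.diff(self.delta_a) < -1e-12):
            raise InputError("crack extension must be non-decreasing")
        if np.any(self.delta_a < -1e-12):
            raise InputError("crack extension must be non-negative")
        if self.span <= 0:
            raise InputError("span must be positive")
        duration = self.time[-1] - self.time[0]
        if duration > 60.0:
            warnings.warn(
                f"test duration {duration:.1f} s exceeds the plausible 60 s "
                "time-to-failure window",
                stacklevel=2,
            )

    def load_at_frames(self) -> np.ndarray:
        """Load (N) linearly interpolated at the crack-frame timestamps."""
        return np.interp(self.frame_time, self.time, self.load)


@dataclass(frozen=True)
class EventTriplet:
    """Indices of initiation, peak load and instability on the frame clock."""

    initiation_index: int
    peak_index: int
    instability_index: int

    def __post_init__(self) -> None:
        if not (self.initiation_index <= self.peak_index <= self.instability_index):
            raise EventDetectionError(
                "event ordering violated: initiation <= peak <= instability required, got "
                f"{self.initiation_index}, {self.peak_index}, {self.instability_index}"
            )


EVENT_NAMES = ("initiation", "peak", "instability")


@dataclass(frozen=True)
class ToughnessResult:
    """Toughness triplet with per-event metadata and LEFM diagnostics.

    ``K`` values are in MPa·√m, angles in rad, loads in N; ``lefm_ratio``
    is the plastic-zone radius over the wall thickness.
    """

    K: dict[str, float]
    theta: dict[str, float]
    load: dict[str, float]
    delta_a: dict[str, float]
    lefm_valid: dict[str, bool]
    lefm_ratio: dict[str, float]
    events: EventTriplet

    @property
    def K_init(self) -> float:
        return self.K["initiation"]

    @property
    def K_pl(self) -> float:
        return self.K["peak"]

    @property
    def K_inst(self) -> float:
        return self.K["instability"]

    def to_dict(self) -> dict:
        """JSON-serializable flat view of the result."""
        return {
            "K_init": self.K_init,
            "K_pl": self.K_pl,
            "K_inst": self.K_inst,
            "theta": dict(self.theta),
            "load_N": dict(self.load),
            "delta_a_mm": dict(self.delta_a),
            "lefm_valid": dict(self.lefm_valid),
            "lefm_ratio": dict(self.lefm_ratio),
            "event_indices": {
                "initiation": self.events.initiation_index,
                "peak": self.events.peak_index,
                "instability": self.events.instability_index,
            },
        }

    def summary(self) -> str:
        lines = [
            f"{'event':<12}{'K (MPa*sqrt(m))':>16}{'theta (rad)':>13}"
            f"{'P (N)':>9}{'LEFM':>7}{'r_p/t':>8}"
        ]
        for ev in EVENT_NAMES:
            lines.append(
                f"{ev:<12}{self.K[ev]:>16.3f}{self.theta[ev]:>13.4f}"
                f"{self.load[ev]:>9.2f}{'ok' if self.lefm_valid[ev] else 'NO':>7}"
                f"{self.lefm_ratio[ev]:>8.3f}"
            )
        return "\n".join(lines)


@dataclass(frozen=True)
class EventDetectionConfig:
    """Thresholds for event detection on the crack-frame clock.

    ``initiation_pixels`` is converted to mm through the record's pixel
    size (5 px at 2.2 μm/px → 11 μm, about twice the optical noise
    floor); ``load_drop_fraction`` is the between-frame load drop,
    relative to peak load, that marks unstable growth.
    """

    initiation_pixels: float = 5.0
    initiation_mm: float | None = None   # overrides the pixel rule when set
    load_drop_fraction: float = 0.10

    def initiation_threshold_mm(self, pixel_size_um: float) -> float:
        if self.initiation_mm is not None:
            return float(self.initiation_mm)
        return self.initiation_pixels * pixel_size_um * 1e-3


# ---------------------------------------------------------------------------
# kinematics and stress intensity
# ---------------------------------------------------------------------------

def half_crack_angle(
    notch: NotchGeometry,
    delta_a_proj: float,
    section: CrossSection,
    radius_mode: Literal["mean", "outer"] = "mean",
) -> float:
    """Instantaneous half crack angle from projected surface extension.

    The surface-measured projected extension is treated as arc length at
    the chosen radius: ``theta = theta_0 + delta_a / R``.  The mean
    radius is the default convention; ``radius_mode='outer'`` maps at the
    periosteal surface instead (strategy hook for alternative closed
    forms).  The result is clipped into (0, π) with a warning.
    """
    delta_a_proj = float(delta_a_proj)
    if not math.isfinite(delta_a_proj) or delta_a_proj < 0:
        raise InputError(f"projected crack extension must be >= 0, got {delta_a_proj}")
    radius = section.mean_radius if radius_mode == "mean" else section.outer_radius
    theta = notch.initial_half_angle + delta_a_proj / radius
    if theta >= math.pi:
        warnings.warn(
            f"half crack angle {theta:.3f} rad clipped to just below pi", stacklevel=2
        )
        theta = math.nextafter(math.pi, 0.0)
    return theta


@lru_cache(maxsize=1)
def _load_geometry_table() -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    raw = json.loads(
        resources.files("femurtough.data")
        .joinpath("geometry_factor_table.json")
        .read_text()
    )
    tab = np.asarray(raw["ab_table"], dtype=float)
    return (
        tab[:, 0],
        tab[:, 1],
        np.asarray(raw["angle_coefficients"], dtype=float),
        np.asarray(raw["angle_exponents"], dtype=float),
    )


def geometry_factor(theta: float, ratio: float) -> float:
    """Bending geometry factor F_b for the through-wall circumferential crack.

    ``F_b = 1 + A_b * sum_i c_i (theta/pi)^{e_i}`` where the amplitude
    ``A_b`` is tabulated against ``r = R_m/t`` and linearly interpolated
    between tabulated levels.  ``F_b → 1`` as the crack vanishes and the
    factor grows monotonically with crack angle.
    """
    theta = float(theta)
    ratio = float(ratio)
    levels, amps, coeffs, exps = _load_geometry_table()
    if not (0.0 < theta < math.pi):
        raise RangeError(
            f"half crack angle {theta} rad outside supported window (0, pi)"
        )
    if not (levels[0] <= ratio <= levels[-1]):
        raise RangeError(
            f"R_m/t = {ratio:.3f} outside supported window "
            f"[{levels[0]:g}, {levels[-1]:g}]"
        )
    a_b = float(np.interp(ratio, levels, amps))
    x = theta / math.pi
    return 1.0 + a_b * float(np.sum(coeffs * x ** exps))


def stress_intensity(
    load: float,
    span: float,
    section: CrossSection,
    theta: float,
    f_b: float,
) -> float:
    """Stress intensity factor K in MPa·√m.

    The mid-span three-point bending moment ``M = P S / 4`` produces a
    nominal bending stress ``sigma_b = M / (pi R_m^2 t)`` in the
    thin-walled cylinder; then ``K = F_b sigma_b sqrt(pi R_m theta)``.
    Inputs in N and mm give K in MPa·√mm, converted to MPa·√m here.
    """
    load, span, theta, f_b = map(float, (load, span, theta, f_b))
    for name, v in (("load", load), ("span", span), ("theta", theta), ("F_b", f_b)):
        if not math.isfinite(v):
            raise InputError(f"{name} must be finite, got {v}")
    if load < 0:
        raise InputError(f"load must be non-negative, got {load}")
    if not (0.0 < theta < math.pi):
        raise InputError(f"theta must lie in (0, pi), got {theta}")
    moment = load * span / 4.0                                   # N*mm
    sigma_b = moment / (math.pi * section.mean_radius**2 * section.wall_thickness)  # MPa
    k_mpa_sqrt_mm = f_b * sigma_b * math.sqrt(math.pi * section.mean_radius * theta)
    return k_mpa_sqrt_mm * MPA_SQRT_MM_TO_MPA_SQRT_M


# ---------------------------------------------------------------------------
# event detection
# ---------------------------------------------------------------------------

def detect_events(
    record: BendTestRecord,
    config: EventDetectionConfig | None = None,
) -> EventTriplet:
    """Locate initiation, peak load and instability on the frame clock.

    Initiation is the first frame whose crack extension exceeds the
    detection threshold; peak is the frame of maximum (interpolated)
    load; instability is the last frame before a between-frame load drop
    exceeding ``load_drop_fraction`` of the peak load, falling back to
    the final frame with measurable crack extension when no such drop
    exists.
    """
    config = config or EventDetectionConfig()
    if not np.any(record.load > 0):
        raise InputError("load trace is identically zero")
    threshold = config.initiation_threshold_mm(record.pixel_size_um)
    extended = np.flatnonzero(record.delta_a >= threshold)
    if extended.size == 0:
        raise EventDetectionError(
            f"no initiation detected: crack extension never reached "
            f"{threshold * 1e3:.1f} um"
        )
    initiation = int(extended[0])

    frame_load = record.load_at_frames()
    peak = int(np.argmax(frame_load))

    drop = frame_load[:-1] - frame_load[1:]
    big = np.flatnonzero(drop > config.load_drop_fraction * frame_load[peak])
    big = big[big >= peak]
    instability = int(big[0]) if big.size else int(extended[-1])
    instability = max(instability, peak)

    if initiation > peak:
        raise EventDetectionError(
            "crack initiation detected after peak load; record is not a "
            "monotone rise-then-failure test"
        )
    return EventTriplet(initiation, peak, instability)


# ---------------------------------------------------------------------------
# LEFM diagnostics
# ---------------------------------------------------------------------------

def plastic_zone_radius(
    k: float,
    yield_strength: float = DEFAULT_YIELD_STRENGTH_MPA,
    mode: Literal["plane_strain", "plane_stress"] = "plane_strain",
) -> float:
    """Irwin plastic-zone radius in mm.

    Plane strain (default): ``r_p = (K / sigma_y)^2 / (6 pi)``;
    plane stress: ``r_p = (K / sigma_y)^2 / (2 pi)``.  K in MPa·√m and
    yield strength in MPa give the radius in meters, returned in mm.
    """
    k = float(k)
    yield_strength = float(yield_strength)
    if yield_strength <= 0:
        raise InputError("yield strength must be positive")
    if k < 0 or not math.isfinite(k):
        raise InputError(f"K must be finite and non-negative, got {k}")
    denom = 6.0 * math.pi if mode == "plane_strain" else 2.0 * math.pi
    r_p_m = (k / yield_strength) ** 2 / denom
    return r_p_m * 1e3


def lefm_validity(
    k: float,
    section: CrossSection,
    notch: NotchGeometry | None = None,
    yield_strength: float = DEFAULT_YIELD_STRENGTH_MPA,
    cutoff_fraction: float = 0.1,
    mode: Literal["plane_strain", "plane_stress"] = "plane_strain",
) -> dict:
    """Small-scale-yielding check for a computed K.

    The measurement is flagged valid when the plastic-zone radius is
    small relative to the wall thickness (default ``r_p <= t/10``); the
    ratio ``r_p / t`` is always reported.  Diagnostic only — invalid
    values are flagged, never rejected.
    """
    r_p = plastic_zone_radius(k, yield_strength, mode)
    ratio = r_p / section.wall_thickness
    return {"valid": bool(ratio <= cutoff_fraction), "ratio": float(ratio)}


# ---------------------------------------------------------------------------
# the triplet
# ---------------------------------------------------------------------------

def toughness_triplet(
    record: BendTestRecord,
    notch: NotchGeometry,
    section: CrossSection,
    config: EventDetectionConfig | None = None,
    yield_strength: float = DEFAULT_YIELD_STRENGTH_MPA,
    radius_mode: Literal["mean", "outer"] = "mean",
) -> ToughnessResult:
    """Full analysis of one bend test: events, angles, K triplet, LEFM flags."""
    events = detect_events(record, config)
    frame_load = record.load_at_frames()
    ratio = section.radius_thickness_ratio

    K: dict[str, float] = {}
    theta: dict[str, float] = {}
    load: dict[str, float] = {}
    delta_a: dict[str, float] = {}
    valid: dict[str, bool] = {}
    vratio: dict[str, float] = {}
    for name, idx in zip(
        EVENT_NAMES,
        (events.initiation_index, events.peak_index, events.instability_index),
    ):
        da = float(record.delta_a[idx])
        th = half_crack_angle(notch, da, section, radius_mode=radius_mode)
        fb = geometry_factor(th, ratio)
        p = float(frame_load[idx])
        k = stress_intensity(p, record.span, section, th, fb)
        flags = lefm_validity(k, section, notch, yield_strength)
        K[name], theta[name], load[name], delta_a[name] = k, th, p, da
        valid[name], vratio[name] = flags["valid"], flags["ratio"]

    return ToughnessResult(
        K=K, theta=theta, load=load, delta_a=delta_a,
        lefm_valid=valid, lefm_ratio=vratio, events=events,
    )


# ---------------------------------------------------------------------------
# fracture pattern
# ---------------------------------------------------------------------------

def fracture_angle(
    notch_root: Sequence[float],
    breakout: Sequence[float],
    long_axis: int = 0,
) -> float:
    """Global fracture angle α in degrees from two sagittal-plane points.

    The line from the pre-notch root to the periosteal breakout point is
    compared with the transverse plane: ``alpha = atan(|Δlong| /
    |Δtransverse|)``, so a perfectly transverse fracture scores 0°.
    ``long_axis`` selects which coordinate (0 or 1) runs along the bone.
    """
    p0 = np.asarray(notch_root, dtype=float)
    p1 = np.asarray(breakout, dtype=float)
    if p0.shape != (2,) or p1.shape != (2,):
        raise InputError("points must be 2D (long-axis, transverse) coordinates")
    d = p1 - p0
    if np.allclose(d, 0.0):
        raise InputError("notch root and breakout coincide; fracture angle undefined")
    d_long = abs(d[long_axis])
    d_trans = abs(d[1 - long_axis])
    return math.degrees(math.atan2(d_long, d_trans))
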