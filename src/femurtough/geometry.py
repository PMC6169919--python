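"""Idealized cross-section and notch geometry for the femoral mid-diaphysis.

The diaphysis is modelled as a thin annular cylinder: mean radius ``R_m``
and wall thickness ``t`` anchor every stress-intensity computation.  The
sharp pre-notch is described by its initial half crack angle ``theta_0``
(half the circumferential angle the through-wall crack subtends) and its
depth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import GeometryError

_REL_TOL = 1e-6


@dataclass(frozen=True)
class CrossSection:
    """Annular mid-diaphyseal cross section (lengths in mm).

    Parameters
    ----------
    outer_radius, inner_radius:
        Periosteal and endosteal radii of the equivalent annulus, mm.

    Attributes
    ----------
    mean_radius:
        ``(R_o + R_i) / 2`` in mm.
    wall_thickness:
        ``R_o - R_i`` in mm.
    """

    outer_radius: float
    inner_radius: float
    mean_radius: float = field(init=False)
    wall_thickness: float = field(init=False)

    def __post_init__(self) -> None:
        R_o, R_i = float(self.outer_radius), float(self.inner_radius)
        if not (math.isfinite(R_o) and math.isfinite(R_i)):
            raise GeometryError("radii must be finite")
        if not R_o > R_i > 0:
            raise GeometryError(
                f"require outer_radius > inner_radius > 0, got R_o={R_o}, R_i={R_i}"
            )
        object.__setattr__(self, "mean_radius", 0.5 * (R_o + R_i))
        object.__setattr__(self, "wall_thickness", R_o - R_i)
        if self.radius_thickness_ratio <= 1.0:
            raise GeometryError(
                "mean radius must exceed wall thickness (R_m/t > 1); "
                f"got R_m/t = {self.radius_thickness_ratio:.3f}"
            )

    @classmethod
    def from_mean_and_thickness(cls, mean_radius: float, wall_thickness: float) -> "CrossSection":
        """Build from ``R_m`` and ``t`` instead of the two radii."""
        return cls(mean_radius + wall_thickness / 2.0, mean_radius - wall_thickness / 2.0)

    @property
    def radius_thickness_ratio(self) -> float:
        """Dimensionless ``R_m / t`` controlling the geometry factor."""
        return self.mean_radius / self.wall_thickness


@dataclass(frozen=True)
class NotchGeometry:
    """Sharp pre-notch: initial half crack angle (rad) and depth (mm).

    The two-stage notching protocol (saw then razor) produces a total
    depth around 0.65 mm, but depth is specimen specific and not
    validated against that figure.
    """

    initial_half_angle: float
    notch_depth: float

    def __post_init__(self) -> None:
        th = float(self.initial_half_angle)
        if not (0.0 < th < math.pi / 2.0):
            raise GeometryError(
                f"initial half crack angle must lie in (0, pi/2); got {th}"
            )
        if not self.notch_depth > 0:
            raise GeometryError("notch depth must be positive")
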