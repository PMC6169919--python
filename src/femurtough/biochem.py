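"""Matrix biochemistry from plate-reader fluorescence tables.

Pentosidine is quantified against a quinine sulfate (QS) standard curve
(λ_ex/λ_em 335/385 nm) and expressed as μg QS-equivalents per μg
collagen; nonspecific AGEs are bulk fluorescence (370/440 nm, plate
gain 100) per μg collagen; collagen mass comes from a hydroxyproline
assay assuming collagen is 13.5% hydroxyproline by mass.  The
mineral-to-matrix ratio divides μCT-derived bone mineral content by the
collagen mass.

nsAGE fluorescence is comparable only within a plate; keep a batch
column when combining plates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import CalibrationError, InputError, NormalizationError

#: hydroxyproline mass fraction of type I collagen
HYDROXYPROLINE_FRACTION = 0.135

#: replicate coefficient-of-variation QC limit
DEFAULT_CV_LIMIT = 0.15


@dataclass(frozen=True)
class StandardCurve:
    """OLS fit of fluorescence on concentration, with inverse prediction."""

    slope: float
    intercept: float
    r_squared: float
    top_standard: float  # highest standard concentration fitted

    def predict(self, concentration: float) -> float:
        return self.intercept + self.slope * float(concentration)

    def inverse(self, fluorescence: float) -> float:
        """Concentration whose fitted fluorescence equals the reading.

        Readings above 120% of the top standard's fitted fluorescence
        are outside the calibrated range: a warning is issued and NaN
        returned rather than extrapolating.
        """
        conc = (float(fluorescence) - self.intercept) / self.slope
        if conc > 1.2 * self.top_standard:
            warnings.warn(
                f"reading implies {conc:.3g}, beyond 120% of the top standard "
                f"({self.top_standard:g}); refusing to extrapolate",
                stacklevel=2,
            )
            return float("nan")
        return conc


def fit_standard_curve(
    concentrations: Sequence[float], fluorescence: Sequence[float]
) -> StandardCurve:
    """Fit the linear standard curve (e.g. quinine sulfate for pentosidine)."""
    conc = np.asarray(concentrations, dtype=float)
    fluo = np.asarray(fluorescence, dtype=float)
    if conc.size != fluo.size:
        raise InputError("concentration and fluorescence lengths differ")
    if np.unique(conc).size < 3:
        raise CalibrationError("need standards at >= 3 distinct concentrations")
    # tolerate float-noise negatives around zero (blank-subtracted wells)
    if np.any(fluo < -1e-9 * max(1.0, float(np.abs(fluo).max()))):
        raise InputError("fluorescence readings must be non-negative")
    fit = stats.linregress(conc, fluo)
    if fit.slope <= 0:
        raise CalibrationError(
            f"standard curve slope is not positive ({fit.slope:.3g}); "
            "standards are non-monotone"
        )
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        top_standard=float(conc.max()),
    )


def collagen_from_hydroxyproline(hyp_mass_ug: float) -> float:
    """Collagen mass (μg) from hydroxyproline mass, at 13.5% by mass."""
    hyp = float(hyp_mass_ug)
    if hyp < 0:
        raise InputError(f"hydroxyproline mass must be >= 0, got {hyp}")
    return hyp / HYDROXYPROLINE_FRACTION


@dataclass(frozen=True)
class ReplicateSummary:
    mean: float
    cv: float | None     # None for a single reading
    flagged: bool
    note: str = ""


def replicate_reduce(
    readings: Sequence[float], cv_limit: float = DEFAULT_CV_LIMIT
) -> ReplicateSummary:
    """Mean of technical replicates with a CV quality flag.

    Triplicates with CV above the limit (default 15%) are flagged; a
    single reading passes through annotated ``no-replicate``.
    """
    vals = np.asarray(readings, dtype=float)
    if vals.size < 1:
        raise InputError("need at least one reading")
    mean = float(vals.mean())
    if vals.size == 1:
        return ReplicateSummary(mean=mean, cv=None, flagged=False, note="no-replicate")
    cv = float(vals.std(ddof=1) / mean) if mean != 0 else float("inf")
    return ReplicateSummary(mean=mean, cv=cv, flagged=bool(cv > cv_limit))


def normalize_age(analyte_amount: float, collagen_ug: float) -> float:
    """Analyte per μg collagen (μg QS/μg for pentosidine, FU/μg for nsAGE)."""
    if not collagen_ug > 0:
        raise NormalizationError(
            f"collagen mass must be positive to normalize, got {collagen_ug}"
        )
    if analyte_amount < 0:
        raise InputError("analyte amount must be non-negative")
    return float(analyte_amount) / float(collagen_ug)


def analyze_plate(plate, standards, cv_limit: float = DEFAULT_CV_LIMIT):
    """Per-sample biochemistry from tidy plate and standards tables.

    ``plate`` has columns (sample, replicate, channel, fluorescence) with
    channels ``pentosidine`` (triplicate, QS standards), ``nsAGE``
    (single reading) and ``hydroxyproline`` (triplicate, μg standards).
    ``standards`` has columns (channel, concentration, fluorescence).
    Returns one row per sample: collagen mass, pentosidine per collagen,
    nsAGE per collagen and replicate QC flags.
    """
    import pandas as pd

    curves = {}
    for channel, grp in standards.groupby("channel"):
        curves[channel] = fit_standard_curve(
            grp["concentration"].to_numpy(), grp["fluorescence"].to_numpy()
        )
    rows = []
    for sample, grp in plate.groupby("sample"):
        by_channel = {ch: g["fluorescence"].to_numpy() for ch, g in grp.groupby("channel")}
        for needed in ("hydroxyproline", "pentosidine"):
            if needed not in by_channel:
                raise InputError(f"sample {sample!r}: missing channel {needed!r}")
            if needed not in curves:
                raise CalibrationError(f"no standards for channel {needed!r}")
        hyp = replicate_reduce(by_channel["hydroxyproline"], cv_limit)
        pen = replicate_reduce(by_channel["pentosidine"], cv_limit)
        collagen = collagen_from_hydroxyproline(curves["hydroxyproline"].inverse(hyp.mean))
        pen_qs = curves["pentosidine"].inverse(pen.mean)
        row = {
            "sample": sample,
            "collagen_ug": collagen,
            "pentosidine_per_collagen": normalize_age(pen_qs, collagen),
            "hyp_cv_flag": hyp.flagged,
            "pentosidine_cv_flag": pen.flagged,
        }
        if "nsAGE" in by_channel:
            ns = replicate_reduce(by_channel["nsAGE"], cv_limit)
            row["nsAGE_per_collagen"] = normalize_age(ns.mean, collagen)
            row["nsAGE_note"] = ns.note
        rows.append(row)
    return pd.DataFrame(rows)


def mineral_to_matrix(bone_mineral_content_ug: float, collagen_ug: float) -> float:
    """Mineral-to-matrix ratio: μCT bone mineral content over collagen mass."""
    if not collagen_ug > 0:
        raise NormalizationError(
            f"collagen mass must be positive, got {collagen_ug}"
        )
    if bone_mineral_content_ug < 0:
        raise InputError("bone mineral content must be non-negative")
    return float(bone_mineral_content_ug) / float(collagen_ug)
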