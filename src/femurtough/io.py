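"""File formats, run configuration and the end-to-end study runner.

Bend tests travel as two CSVs (a dense load trace and a sparser crack
frame series) plus a JSON geometry sidecar; μCT sections as TIFF or CSV
grids with a JSON calibration sidecar; cohort tables as tidy long-format
CSV.  ``run_study`` regenerates a full synthetic study from a
calibration and writes the per-specimen and inference outputs with a
reproducibility manifest (seed, config hash, package version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import SchemaError
from .fracture import (
    BendTestRecord,
    EventDetectionConfig,
    toughness_triplet,
)
from .geometry import CrossSection, NotchGeometry
from .morphometry import SectionImage, analyze_section
from .simulate import (
    DEFAULT_NOTCH,
    DEFAULT_SECTION,
    StudyCalibration,
    gen_bend_test,
    gen_cohort,
    gen_paired_femurs,
    gen_ribosylation,
    gen_section_mask,
    bed_linear_quadratic,
)
from . import stats as fstats

_RECORD_COLUMNS = ("time_s", "load_N", "displacement_mm")
_FRAME_COLUMNS = ("frame_time_s", "delta_a_mm")


def _require_columns(df: pd.DataFrame, cols: tuple[str, ...], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {missing}; found {list(df.columns)}")


def read_bend_record(
    record_csv: str | Path,
    frames_csv: str | Path,
    geometry_json: str | Path,
) -> tuple[BendTestRecord, NotchGeometry, CrossSection]:
    """Load a synchronized bend test from its two CSVs and geometry JSON.

    Rows are re-sorted by time, so shuffled exports are accepted; any
    remaining invariant violation (non-monotone crack extension,
    negative loads) raises with a column-level message.
    """
    rec = pd.read_csv(record_csv)
    frames = pd.read_csv(frames_csv)
    _require_columns(rec, _RECORD_COLUMNS, "record CSV")
    _require_columns(frames, _FRAME_COLUMNS, "frames CSV")
    rec = rec.sort_values("time_s")
    frames = frames.sort_values("frame_time_s")
    geo = json.loads(Path(geometry_json).read_text())
    for key in ("R_o_mm", "R_i_mm", "theta0_rad", "notch_depth_mm"):
        if key not in geo:
            raise SchemaError(f"geometry JSON: missing key {key!r}")
    section = CrossSection(outer_radius=geo["R_o_mm"], inner_radius=geo["R_i_mm"])
    notch = NotchGeometry(
        initial_half_angle=geo["theta0_rad"], notch_depth=geo["notch_depth_mm"]
    )
    record = BendTestRecord(
        time=rec["time_s"].to_numpy(),
        load=rec["load_N"].to_numpy(),
        displacement=rec["displacement_mm"].to_numpy(),
        frame_time=frames["frame_time_s"].to_numpy(),
        delta_a=frames["delta_a_mm"].to_numpy(),
        span=float(geo.get("span_mm", 8.0)),
        pixel_size_um=float(geo.get("pixel_size_um", 2.2)),
    )
    return record, notch, section


def write_bend_record(
    record: BendTestRecord,
    notch: NotchGeometry,
    section: CrossSection,
    record_csv: str | Path,
    frames_csv: str | Path,
    geometry_json: str | Path,
) -> None:
    """Inverse of :func:`read_bend_record` (round-trip identity)."""
    pd.DataFrame(
        {
            "time_s": record.time,
            "load_N": record.load,
            "displacement_mm": record.displacement,
        }
    ).to_csv(record_csv, index=False)
    pd.DataFrame(
        {"frame_time_s": record.frame_time, "delta_a_mm": record.delta_a}
    ).to_csv(frames_csv, index=False)
    Path(geometry_json).write_text(
        json.dumps(
            {
                "R_o_mm": section.outer_radius,
                "R_i_mm": section.inner_radius,
                "theta0_rad": notch.initial_half_angle,
                "notch_depth_mm": notch.notch_depth,
                "span_mm": record.span,
                "pixel_size_um": record.pixel_size_um,
            },
            indent=2,
        )
    )


def read_section_image(
    image_path: str | Path, calibration_json: str | Path | None = None
) -> SectionImage:
    """Load a density slice from TIFF or CSV, applying a calibration sidecar.

    The sidecar maps raw grid values to mg HA/cm³ through
    ``density = slope * raw + intercept`` and carries ``pixel_size_um``.
    """
    path = Path(image_path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        raw = np.asarray(tifffile.imread(path), dtype=float)
        if raw.ndim == 3:  # stack: average slices
            raw = raw.mean(axis=0)
    else:
        raw = np.loadtxt(path, delimiter=",", dtype=float)
    slope, intercept, px = 1.0, 0.0, 12.0
    if calibration_json is not None:
        calib = json.loads(Path(calibration_json).read_text())
        slope = float(calib.get("slope", 1.0))
        intercept = float(calib.get("intercept", 0.0))
        px = float(calib.get("pixel_size_um", 12.0))
    return SectionImage(density=np.clip(slope * raw + intercept, 0.0, None),
                        pixel_size_um=px)


# ---------------------------------------------------------------------------
# study runner
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration for an end-to-end synthetic study run."""

    seed: int = 0
    output_dir: str | Path = "study_out"
    calibration_path: str | Path | None = None  # None -> packaged defaults
    initiation_pixels: float = 5.0
    load_drop_fraction: float = 0.10
    lefm_cutoff_fraction: float = 0.10
    density_threshold: float = 654.0

    def __post_init__(self) -> None:
        for name in ("initiation_pixels", "load_drop_fraction",
                     "lefm_cutoff_fraction", "density_threshold"):
            if getattr(self, name) <= 0:
                raise SchemaError(f"threshold {name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        # output_dir is excluded: where the bundle lands must not change
        # its content hash
        payload = {
            k: str(v)
            for k, v in dataclasses.asdict(self).items()
            if k != "output_dir"
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def run_study(config: RunConfig) -> dict:
    """Simulate and analyze the full study; write the report bundle.

    Generates the longitudinal cohort, the paired devitalized design and
    the ribosylation series from the calibration, runs the statistics
    battery, analyzes one forward-modelled bend test and one synthetic
    μCT section, and writes tidy CSV/JSON outputs plus a manifest with
    the seed and config hash so reruns are bit-reproducible.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    calibration = (
        StudyCalibration.from_yaml(config.calibration_path)
        if config.calibration_path
        else StudyCalibration.default()
    )
    seed = int(config.seed)

    cohort, cohort_truth = gen_cohort(calibration, seed=seed)
    paired, paired_truth = gen_paired_femurs(calibration, seed=seed + 1)
    ribose, ribose_truth = gen_ribosylation(calibration, seed=seed + 2)
    cohort.to_csv(out / "cohort.csv", index=False)
    paired.to_csv(out / "paired.csv", index=False)
    ribose.to_csv(out / "ribosylation.csv", index=False)

    tp_frames = []
    ancova_results = {}
    for outcome in cohort["outcome"].unique():
        tp = fstats.timepoint_tests(cohort, outcome).reset_index()
        tp.insert(0, "outcome", outcome)
        tp_frames.append(tp)
        ancova_results[outcome] = dataclasses.asdict(fstats.ancova(cohort, outcome))
    pd.concat(tp_frames, ignore_index=True).to_csv(out / "timepoint_tests.csv", index=False)

    paired_results = {
        outcome: fstats.paired_tests(paired, outcome)
        for outcome in paired["outcome"].unique()
    }
    ribose_results = {}
    for outcome in ribose["outcome"].unique():
        sub = ribose[ribose["outcome"] == outcome]
        ribose_results[outcome] = dataclasses.asdict(
            fstats.linfit(sub["day"], sub["value"])
        )

    record, bend_truth = gen_bend_test(seed=seed + 3)
    tough = toughness_triplet(
        record,
        notch=DEFAULT_NOTCH,
        section=DEFAULT_SECTION,
        config=EventDetectionConfig(
            initiation_pixels=config.initiation_pixels,
            load_drop_fraction=config.load_drop_fraction,
        ),
    )
    image, section_truth = gen_section_mask(seed=seed + 4)
    morph = analyze_section(image, threshold=config.density_threshold)

    stats_bundle = {
        "ancova": ancova_results,
        "paired_tests": paired_results,
        "ribosylation_regressions": ribose_results,
        "bed_gy": bed_linear_quadratic(
            calibration.bed["n_fractions"],
            calibration.bed["dose_per_fraction_gy"],
            calibration.bed["alpha_beta_gy"],
        ),
        "example_toughness": tough.to_dict(),
        "example_morphology": morph.to_dict(),
    }
    (out / "statistics.json").write_text(json.dumps(stats_bundle, indent=2, default=float))

    manifest = {
        "package_version": __version__,
        "seed": seed,
        "config_hash": config.digest(),
        "planted_truth": {
            "cohort": cohort_truth,
            "paired": paired_truth,
            "ribosylation": ribose_truth,
            "bend_test": bend_truth,
            "section": {k: v for k, v in section_truth.items() if k != "mask"},
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return stats_bundle
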