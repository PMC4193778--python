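"""Delimited-text readers/writers for every pipeline table.

All tabular I/O is comma-separated UTF-8 with a header row; pixel and
cm coordinates round-trip at 1e-6 precision.  Readers validate the
schema (required columns, parseable numerics, unique primary keys) and
raise :class:`~scallopsize.errors.SchemaError` naming the offending
column or key.  Configs and fitted models are structured text (YAML).

Schemas
-------
grid:          point_id, x_d_px, y_d_px, x_u_cm, y_u_cm
metadata:      image_id, survey_id, transect_id, timestamp, lat, lon,
               altitude_m, depth_m, pitch_deg, roll_deg
annotations:   shell_id, image_id, tip_x_px, tip_y_px, base_x_px,
               base_y_px, status, partially_visible
measurements:  shell_id, image_id, survey_id, transect_id,
               raw_height_cm, corrected_height_cm, altitude_m, scale_ratio
truth:         shell_id, true_height_cm, base_height_cm, survey_effect,
               transect_effect, frame_effect
heights:       height_cm (one column; e.g. dredge samples)
distribution:  source, bin_lo_cm, bin_hi_cm, proportion, lower, upper
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import GridCorrespondence
from .errors import SchemaError

__all__ = [
    "SCHEMAS",
    "read_table",
    "write_table",
    "read_grid",
    "write_grid",
    "read_heights",
    "write_heights",
    "PipelineConfig",
]

_FLOAT_FMT = "%.10g"

#: required columns, numeric columns, primary-key column per table kind
SCHEMAS: dict[str, dict] = {
    "grid": {
        "columns": ["point_id", "x_d_px", "y_d_px", "x_u_cm", "y_u_cm"],
        "numeric": ["x_d_px", "y_d_px", "x_u_cm", "y_u_cm"],
        "key": "point_id",
    },
    "metadata": {
        "columns": ["image_id", "survey_id", "transect_id", "timestamp",
                    "lat", "lon", "altitude_m", "depth_m", "pitch_deg",
                    "roll_deg"],
        "numeric": ["lat", "lon", "altitude_m", "depth_m", "pitch_deg",
                    "roll_deg"],
        "key": "image_id",
    },
    "annotations": {
        "columns": ["shell_id", "image_id", "tip_x_px", "tip_y_px",
                    "base_x_px", "base_y_px", "status", "partially_visible"],
        "numeric": ["tip_x_px", "tip_y_px", "base_x_px", "base_y_px"],
        "key": "shell_id",
    },
    "measurements": {
        "columns": ["shell_id", "image_id", "survey_id", "transect_id",
                    "raw_height_cm", "corrected_height_cm", "altitude_m",
                    "scale_ratio"],
        "numeric": ["raw_height_cm", "corrected_height_cm", "altitude_m",
                    "scale_ratio"],
        "key": "shell_id",
    },
    "truth": {
        "columns": ["shell_id", "true_height_cm", "base_height_cm",
                    "survey_effect", "transect_effect", "frame_effect"],
        "numeric": ["true_height_cm", "base_height_cm", "survey_effect",
                    "transect_effect", "frame_effect"],
        "key": "shell_id",
    },
    "heights": {
        "columns": ["height_cm"],
        "numeric": ["height_cm"],
        "key": None,
    },
    "distribution": {
        "columns": ["source", "bin_lo_cm", "bin_hi_cm", "proportion",
                    "lower", "upper"],
        "numeric": ["bin_lo_cm", "bin_hi_cm", "proportion"],
        "key": None,
    },
}


def read_table(path, kind: str) -> pd.DataFrame:
    """Read and validate one of the known table kinds."""
    if kind not in SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}")
    schema = SCHEMAS[kind]
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # noqa: BLE001 - rewrap for exit-code mapping
        raise SchemaError(f"cannot read {path}: {exc}") from exc
    missing = [c for c in schema["columns"] if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {', '.join(missing)}"
        )
    for col in schema["numeric"]:
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = df.index[
                pd.to_numeric(df[col], errors="coerce").isna()
            ].tolist()[:3]
            raise SchemaError(
                f"{path}: unparseable numeric in column {col!r} "
                f"(row index {bad})"
            ) from exc
    key = schema["key"]
    if key is not None:
        dup = df[key][df[key].duplicated()]
        if len(dup):
            raise SchemaError(
                f"{path}: duplicated {key} {dup.iloc[0]!r}"
            )
    if "partially_visible" in df.columns:
        df["partially_visible"] = (
            df["partially_visible"].astype(str).str.lower()
            .isin(["true", "1", "yes"])
        )
    return df[schema["columns"]]


def write_table(df: pd.DataFrame, path, kind: str) -> None:
    """Write a table in its schema's column order."""
    schema = SCHEMAS[kind]
    missing = [c for c in schema["columns"] if c not in df.columns]
    if missing:
        raise SchemaError(
            f"cannot write {kind}: missing column(s) {', '.join(missing)}"
        )
    df[schema["columns"]].to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_grid(
    path, grid_spacing_cm: float, frame_altitude_m: float
) -> GridCorrespondence:
    """Read calibration correspondences; spacing and calibration
    altitude come from configuration (not stored per row)."""
    df = read_table(path, "grid")
    return GridCorrespondence(
        distorted_points=df[["x_d_px", "y_d_px"]].to_numpy(float),
        reference_points=df[["x_u_cm", "y_u_cm"]].to_numpy(float),
        grid_spacing_cm=grid_spacing_cm,
        frame_altitude_m=frame_altitude_m,
        point_ids=df["point_id"].to_numpy(),
    )


def write_grid(grid: GridCorrespondence, path) -> None:
    pd.DataFrame(
        {
            "point_id": grid.point_ids,
            "x_d_px": grid.distorted_points[:, 0],
            "y_d_px": grid.distorted_points[:, 1],
            "x_u_cm": grid.reference_points[:, 0],
            "y_u_cm": grid.reference_points[:, 1],
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_heights(path) -> np.ndarray:
    """One-column height list (e.g. dredge-measured shells), cm."""
    return read_table(path, "heights")["height_cm"].to_numpy(float)


def write_heights(heights, path) -> None:
    pd.DataFrame({"height_cm": np.asarray(heights, float)}).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


@dataclass
class PipelineConfig:
    """Scenario/run configuration for the CLI pipeline.

    Paths are resolved relative to the config file's directory.  All
    randomness flows from the named seeds here; there is no hidden
    global state.
    """

    # paths (inputs may be absent when the simulate stage creates them)
    grid_path: str = "grid.csv"
    metadata_path: str = "metadata.csv"
    annotations_path: str = "annotations.csv"
    truth_path: str = "truth.csv"
    dredge_heights_path: str | None = None
    # calibration / measurement
    h_frame_m: float = 2.0
    grid_spacing_cm: float = 15.0
    altitude_window: tuple[float, float] = (1.5, 2.5)
    n_frames_per_transect: int = 25
    apply_tilt_correction: bool = False
    calibration_mode: str = "means"  # or "individuals"
    include_cross_term: bool = True
    # distribution
    bin_lo_cm: float = 2.0
    bin_hi_cm: float = 10.0
    bin_width_cm: float = 0.5
    confidence_level: float = 0.90
    boundary_mixture_lrt: bool = False
    # simulation
    seed: int = 0
    pincushion_strength: float = 0.02
    camera: dict = field(default_factory=dict)
    population: dict = field(default_factory=dict)
    plan: dict = field(default_factory=dict)
    groundtruth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lo, hi = self.altitude_window
        if not lo < hi:
            raise SchemaError(
                f"altitude_window must satisfy lo < hi, got [{lo}, {hi}]"
            )
        if self.h_frame_m <= 0:
            raise SchemaError("h_frame_m must be > 0")
        if self.n_frames_per_transect < 1:
            raise SchemaError("n_frames_per_transect must be >= 1")
        if self.calibration_mode not in ("means", "individuals"):
            raise SchemaError(
                "calibration_mode must be 'means' or 'individuals'"
            )
        if not 0 < self.confidence_level <= 1:
            raise SchemaError("confidence_level must be in (0, 1]")
        if self.bin_width_cm <= 0 or self.bin_lo_cm >= self.bin_hi_cm:
            raise SchemaError("invalid bin configuration")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(
                f"{path}: unknown config key(s) {', '.join(sorted(unknown))}"
            )
        if "altitude_window" in raw:
            raw["altitude_window"] = tuple(raw["altitude_window"])
        cfg = cls(**raw)
        base = path.parent
        for attr in ("grid_path", "metadata_path", "annotations_path",
                     "truth_path", "dredge_heights_path"):
            val = getattr(cfg, attr)
            if val is not None and not Path(val).is_absolute():
                setattr(cfg, attr, str(base / val))
        return cfg

    def to_yaml(self, path) -> None:
        payload = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)
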