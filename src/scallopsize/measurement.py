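"""Shell-height estimation from annotated pixel endpoints.

An annotator records the pixel position of the tip of the valve and the
umbo (hinge base) of each scallop shell visible in a frame.  Both points
are mapped through the lens correction to physical coordinates in the
calibration-grid plane (cm at the calibration altitude ``h_frame``).
Their Euclidean distance ``P`` is then rescaled for the altitude at
which the frame was actually taken,

    S = P * h_photo / h_frame,

which is the similar-triangles scaling of a downward camera over a flat
seabed.  Ground-truthing against shells of known height shows a roughly
constant underestimation attributable to pixel error (each endpoint can
only be recorded to the nearest pixel, and annotators tend to click
inside the fuzzy shell edge), so a simple linear regression of known on
estimated category means provides the final correction applied to every
individual estimate.

Frame-selection helpers implement the survey protocol: keep frames
inside an altitude window where detail is sufficient, sample a fixed
number of frames per transect at random, and drop dead (decolorized)
shells before any distribution is built.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .calibration import DistortionCorrectionModel
from .errors import (
    ExcludedRecordError,
    InvalidGeometryError,
    JoinError,
    UnderdeterminedFitError,
)
from .footprint import footprint_from_fov, tilted_footprint

logger = logging.getLogger(__name__)

__all__ = [
    "SizeCalibration",
    "measure_shell",
    "measure_shells",
    "fit_size_calibration",
    "apply_calibration",
    "filter_frames",
    "sample_frames",
    "exclude_dead",
]


@dataclass(frozen=True)
class SizeCalibration:
    """Linear ground-truth correction ``known = intercept + slope * estimated``.

    Fitted from paired category means of planted shells of known height
    versus their photogrammetric estimates; applied to every individual
    raw estimate downstream.
    """

    slope: float
    intercept_cm: float
    n_categories: int
    category_means: pd.DataFrame | None = None  # columns known_cm, estimated_cm

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise UnderdeterminedFitError(
                f"calibration slope must be > 0, got {self.slope}"
            )
        if self.n_categories < 2:
            raise UnderdeterminedFitError("need >= 2 calibration categories")

    @classmethod
    def identity(cls) -> "SizeCalibration":
        return cls(slope=1.0, intercept_cm=0.0, n_categories=2)


def _tilt_factors(
    metadata: Mapping, h: float, fov_x_deg: float, fov_y_deg: float
) -> tuple[float, float]:
    """Per-axis footprint inflation factors D'/D for one frame.

    Roll stretches the across-track (image x) axis, pitch the
    along-track (image y) axis.
    """
    fx, fy = 1.0, 1.0
    Dx = footprint_from_fov(fov_x_deg, h)
    Dy = footprint_from_fov(fov_y_deg, h)
    fx = tilted_footprint(Dx, h, float(metadata["roll_deg"])) / Dx
    fy = tilted_footprint(Dy, h, float(metadata["pitch_deg"])) / Dy
    return fx, fy


def measure_shell(
    annotation: Mapping,
    metadata: Mapping,
    model: DistortionCorrectionModel,
    h_frame_m: float,
    apply_tilt_correction: bool = False,
    fov_x_deg: float | None = None,
    fov_y_deg: float | None = None,
) -> float:
    """Raw shell height in cm for one annotated shell.

    ``annotation`` needs tip_x_px/tip_y_px/base_x_px/base_y_px (and
    optionally partially_visible), ``metadata`` needs altitude_m (plus
    pitch_deg/roll_deg when tilt correction is requested).

    Raises :class:`ExcludedRecordError` for partially visible shells and
    :class:`InvalidGeometryError` for degenerate inputs.
    """
    if bool(annotation.get("partially_visible", False)):
        raise ExcludedRecordError(
            f"shell {annotation.get('shell_id', '?')} is partially visible; "
            "excluded from measurement by protocol"
        )
    h_photo = float(metadata["altitude_m"])
    if not (h_photo > 0 and h_frame_m > 0):
        raise InvalidGeometryError("altitudes must be > 0")
    tip = (float(annotation["tip_x_px"]), float(annotation["tip_y_px"]))
    base = (float(annotation["base_x_px"]), float(annotation["base_y_px"]))
    if tip == base:
        raise InvalidGeometryError("tip and base pixel points coincide")
    pts = model.predict(np.array([tip, base]))
    dx, dy = pts[0, 0] - pts[1, 0], pts[0, 1] - pts[1, 1]
    if apply_tilt_correction:
        if fov_x_deg is None or fov_y_deg is None:
            raise InvalidGeometryError(
                "tilt correction requires the camera field of view per axis"
            )
        fx, fy = _tilt_factors(metadata, h_photo, fov_x_deg, fov_y_deg)
        dx, dy = dx * fx, dy * fy
    P = float(np.hypot(dx, dy))
    return P * h_photo / h_frame_m


def measure_shells(
    annotations: pd.DataFrame,
    metadata: pd.DataFrame,
    model: DistortionCorrectionModel,
    h_frame_m: float,
    calibration: SizeCalibration | None = None,
    apply_tilt_correction: bool = False,
    fov_x_deg: float | None = None,
    fov_y_deg: float | None = None,
) -> pd.DataFrame:
    """Measure every usable annotated shell in a survey.

    Joins annotations to frame metadata on ``image_id`` (an annotation
    without a metadata record raises :class:`JoinError`), silently drops
    partially visible shells (logged), and returns the measurement table
    with columns shell_id, image_id, survey_id, transect_id,
    raw_height_cm, corrected_height_cm, altitude_m, scale_ratio.  When no
    ``calibration`` is given, corrected equals raw.
    """
    if h_frame_m <= 0:
        raise InvalidGeometryError("h_frame_m must be > 0")
    ann = annotations.copy()
    n_partial = 0
    if "partially_visible" in ann.columns:
        mask = ann["partially_visible"].astype(bool)
        n_partial = int(mask.sum())
        ann = ann.loc[~mask]
    if n_partial:
        logger.info("excluded %d partially visible shells", n_partial)

    missing = set(ann["image_id"]) - set(metadata["image_id"])
    if missing:
        raise JoinError(
            f"{len(missing)} annotated image(s) have no metadata record, "
            f"e.g. {sorted(missing)[:3]}"
        )
    meta_cols = ["image_id", "survey_id", "transect_id", "altitude_m"]
    if apply_tilt_correction:
        meta_cols += ["pitch_deg", "roll_deg"]
    merged = ann.merge(metadata[meta_cols], on="image_id", how="inner")

    if (merged["altitude_m"] <= 0).any():
        raise InvalidGeometryError("non-positive altitude in metadata")
    tips = model.predict(merged[["tip_x_px", "tip_y_px"]].to_numpy(float))
    bases = model.predict(merged[["base_x_px", "base_y_px"]].to_numpy(float))
    d = tips - bases
    if apply_tilt_correction:
        if fov_x_deg is None or fov_y_deg is None:
            raise InvalidGeometryError(
                "tilt correction requires the camera field of view per axis"
            )
        factors = np.array(
            [
                _tilt_factors(row, row["altitude_m"], fov_x_deg, fov_y_deg)
                for _, row in merged.iterrows()
            ]
        )
        d = d * factors
    span_cm = np.hypot(d[:, 0], d[:, 1])
    if np.any(span_cm <= 0):
        bad = merged.loc[span_cm <= 0, "shell_id"].tolist()
        raise InvalidGeometryError(
            f"zero-length annotation (tip == base) for shell(s) {bad[:3]}"
        )
    scale = merged["altitude_m"].to_numpy(float) / h_frame_m
    raw = span_cm * scale
    corrected = apply_calibration(calibration, raw) if calibration else raw
    out = pd.DataFrame(
        {
            "shell_id": merged["shell_id"],
            "image_id": merged["image_id"],
            "survey_id": merged["survey_id"],
            "transect_id": merged["transect_id"],
            "raw_height_cm": raw,
            "corrected_height_cm": corrected,
            "altitude_m": merged["altitude_m"],
            "scale_ratio": scale,
        }
    )
    logger.info("measured %d shells", len(out))
    return out


def fit_size_calibration(
    known_means: Sequence[float], estimated_means: Sequence[float]
) -> SizeCalibration:
    """OLS of known on estimated category means from the ground-truthing
    experiment (``known = intercept + slope * estimated``)."""
    known = np.asarray(known_means, dtype=float)
    est = np.asarray(estimated_means, dtype=float)
    if known.shape != est.shape or known.ndim != 1:
        raise UnderdeterminedFitError("known/estimated lists must align")
    if len(known) < 2:
        raise UnderdeterminedFitError(
            f"need >= 2 size categories to fit a line, got {len(known)}"
        )
    if np.ptp(est) == 0:
        raise UnderdeterminedFitError("estimated means have zero variance")
    res = sm.OLS(known, sm.add_constant(est)).fit()
    intercept, slope = res.params
    return SizeCalibration(
        slope=float(slope),
        intercept_cm=float(intercept),
        n_categories=len(known),
        category_means=pd.DataFrame(
            {"known_cm": known, "estimated_cm": est}
        ),
    )


def apply_calibration(cal: SizeCalibration, raw):
    """Corrected height(s) ``intercept + slope * raw`` (array-friendly)."""
    return cal.intercept_cm + cal.slope * np.asarray(raw, dtype=float)


def filter_frames(
    metadata: pd.DataFrame, altitude_window: tuple[float, float]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Retain frames taken inside the altitude window ``[lo, hi]`` m.

    Images from too high lack the detail to identify shells; the window
    trades coverage for identifiability.  Returns the retained subset
    and a per-(survey, transect) retention table with columns
    n_available, n_retained, retention_pct.
    """
    lo, hi = altitude_window
    if not lo < hi:
        raise InvalidGeometryError(
            f"altitude window must satisfy lo < hi, got [{lo}, {hi}]"
        )
    if metadata.empty:
        logger.warning("filter_frames called with no metadata records")
        empty = pd.DataFrame(
            columns=["survey_id", "transect_id", "n_available", "n_retained",
                     "retention_pct"]
        )
        return metadata.copy(), empty
    in_window = metadata["altitude_m"].between(lo, hi)
    retained = metadata.loc[in_window].copy()
    grp = metadata.assign(_in=in_window).groupby(
        ["survey_id", "transect_id"], as_index=False
    )
    retention = grp.agg(n_available=("_in", "size"), n_retained=("_in", "sum"))
    retention["retention_pct"] = (
        100.0 * retention["n_retained"] / retention["n_available"]
    )
    logger.info(
        "altitude window [%.2f, %.2f] m retained %d of %d frames",
        lo, hi, len(retained), len(metadata),
    )
    return retained, retention


def sample_frames(
    metadata: pd.DataFrame,
    n_per_transect: int,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Uniform random sample without replacement of ``n_per_transect``
    frames from each (survey, transect); reproducible for a fixed seed.
    Transects with fewer frames contribute all of them (with a warning).
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    parts = []
    for (sid, tid), grp in metadata.groupby(["survey_id", "transect_id"]):
        if len(grp) <= n_per_transect:
            if len(grp) < n_per_transect:
                logger.warning(
                    "survey %s transect %s has only %d frames (< %d); "
                    "taking all", sid, tid, len(grp), n_per_transect,
                )
            parts.append(grp)
        else:
            idx = rng.choice(len(grp), size=n_per_transect, replace=False)
            parts.append(grp.iloc[np.sort(idx)])
    return pd.concat(parts, ignore_index=True)


def exclude_dead(annotations: pd.DataFrame) -> pd.DataFrame:
    """Drop shells flagged dead (decolorized/whitish appearance)."""
    dead = annotations["status"].astype(str).str.lower() == "dead"
    n_dead = int(dead.sum())
    if n_dead:
        logger.info("excluded %d dead shells (%d remain)",
                    n_dead, len(annotations) - n_dead)
    out = annotations.loc[~dead].copy()
    if out.empty and len(annotations):
        logger.warning("all %d annotated shells were dead", len(annotations))
    return out
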