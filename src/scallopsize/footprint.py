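"""Ground footprint of a downward-looking camera under vehicle tilt.

A pinhole camera at altitude ``h`` above a flat seabed images a ground
footprint of dimension ``D`` per axis.  The half-angle of the field of
view along that axis is ``theta = arctan((D/2)/h)``.  When the vehicle
pitches or rolls by ``delta``, the two edge rays of that axis meet the
seabed at ``h*tan(theta+delta)`` and ``h*tan(theta-delta)`` from nadir,
so the footprint stretches to ``D' = h*(tan(theta+delta) +
tan(theta-delta))``, which is >= D and even in ``delta``.  The relative
error ``(D'-D)/D`` quantifies how much uncorrected tilt inflates ground
distances; for the small pitch/roll of a well-trimmed AUV it is a
fraction of a percent and is reported as a diagnostic rather than
applied to individual measurements.

Angles are degrees at every public interface and radians internally.
Pitch tilts the along-track footprint dimension, roll the across-track
dimension; the two axes are treated independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InvalidGeometryError

__all__ = [
    "FrameGeometry",
    "view_half_angle",
    "tilted_footprint",
    "footprint_relative_error",
    "ground_sample_distance",
    "footprint_from_fov",
    "tilt_diagnostics",
]


@dataclass(frozen=True)
class FrameGeometry:
    """Per-frame camera geometry.

    Parameters
    ----------
    altitude_m
        Distance from the seabed at capture (``h``), meters; > 0.
    pitch_deg, roll_deg
        Vehicle tilt about the across-track / along-track axes, degrees.
    footprint_along_m, footprint_across_m
        Nominal ground dimensions ``D`` imaged at ``altitude_m`` with
        zero tilt, meters.
    image_width_px, image_height_px
        Sensor resolution; width maps to the across-track footprint,
        height to the along-track footprint.
    """

    altitude_m: float
    pitch_deg: float
    roll_deg: float
    footprint_along_m: float
    footprint_across_m: float
    image_width_px: int
    image_height_px: int

    def __post_init__(self) -> None:
        if not self.altitude_m > 0:
            raise InvalidGeometryError(
                f"altitude must be > 0 m, got {self.altitude_m}"
            )
        if not (self.footprint_along_m > 0 and self.footprint_across_m > 0):
            raise InvalidGeometryError("footprint dimensions must be > 0")
        if self.image_width_px < 1 or self.image_height_px < 1:
            raise InvalidGeometryError("pixel counts must be >= 1")
        for name, tilt, D in (
            ("pitch", self.pitch_deg, self.footprint_along_m),
            ("roll", self.roll_deg, self.footprint_across_m),
        ):
            half = view_half_angle(D, self.altitude_m)
            if abs(tilt) + half >= 90.0:
                raise InvalidGeometryError(
                    f"|{name}|={abs(tilt)} deg plus view half-angle "
                    f"{half:.2f} deg reaches the horizon; footprint unbounded"
                )


def view_half_angle(D: float, h: float) -> float:
    """Angle in degrees between the outer edge of the field of view and
    the vertical, for a footprint of ground length ``D`` at altitude
    ``h``: ``theta = arctan((D/2)/h)``.
    """
    if not h > 0:
        raise InvalidGeometryError(f"altitude must be > 0, got {h}")
    if D < 0:
        raise InvalidGeometryError(f"footprint must be >= 0, got {D}")
    return math.degrees(math.atan2(D / 2.0, h))


def tilted_footprint(D: float, h: float, delta: float) -> float:
    """Footprint dimension after tilting the camera by ``delta`` degrees.

    ``D' = h * (tan(theta + delta) + tan(theta - delta))`` with
    ``theta = view_half_angle(D, h)``.  Even in ``delta`` and >= D.
    """
    theta = view_half_angle(D, h)
    if theta + abs(delta) >= 90.0:
        raise InvalidGeometryError(
            f"tilt {delta} deg pushes an edge ray past the horizon "
            f"(half-angle {theta:.2f} deg)"
        )
    if delta == 0.0:
        return D
    t = math.radians(theta)
    d = math.radians(abs(delta))  # D' is even in the tilt
    return h * (math.tan(t + d) + math.tan(t - d))


def footprint_relative_error(D: float, h: float, delta: float) -> float:
    """Relative inflation ``(D' - D) / D`` of the footprint due to a tilt
    of ``delta`` degrees.  Zero at delta = 0, nondecreasing in |delta|.
    """
    if D <= 0:
        raise InvalidGeometryError("relative error undefined for D <= 0")
    return (tilted_footprint(D, h, delta) - D) / D


def ground_sample_distance(geometry: FrameGeometry) -> tuple[float, float]:
    """Ground length represented by one pixel, cm, as
    ``(across_cm_per_px, along_cm_per_px)`` =
    ``(footprint_across*100/width_px, footprint_along*100/height_px)``.
    """
    return (
        geometry.footprint_across_m * 100.0 / geometry.image_width_px,
        geometry.footprint_along_m * 100.0 / geometry.image_height_px,
    )


def footprint_from_fov(fov_deg: float, h: float) -> float:
    """Footprint ground dimension for a full angular field of view
    ``fov_deg`` at altitude ``h``: ``D = 2*h*tan(fov/2)``."""
    if not h > 0:
        raise InvalidGeometryError(f"altitude must be > 0, got {h}")
    if not 0 <= fov_deg < 180:
        raise InvalidGeometryError("field of view must lie in [0, 180) deg")
    return 2.0 * h * math.tan(math.radians(fov_deg) / 2.0)


def tilt_diagnostics(geometry: FrameGeometry) -> dict[str, float]:
    """Per-axis footprint inflation for one frame.

    Pitch stretches the along-track dimension, roll the across-track
    dimension.  Returns the tilted dimensions and relative errors; used
    to audit whether tilt is negligible for a survey.
    """
    along = tilted_footprint(
        geometry.footprint_along_m, geometry.altitude_m, geometry.pitch_deg
    )
    across = tilted_footprint(
        geometry.footprint_across_m, geometry.altitude_m, geometry.roll_deg
    )
    return {
        "footprint_along_tilted_m": along,
        "footprint_across_tilted_m": across,
        "relative_error_along": (along - geometry.footprint_along_m)
        / geometry.footprint_along_m,
        "relative_error_across": (across - geometry.footprint_across_m)
        / geometry.footprint_across_m,
    }
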