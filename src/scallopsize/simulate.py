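"""Synthetic camera, seabed population and survey-design generator.

Every input the pipeline consumes — calibration-grid correspondences,
per-frame metadata, shell annotations, ground-truthing records — can be
generated here from models with known parameters, so the whole chain is
testable end to end without real imagery.

Camera model.  A pinhole camera of fixed angular field of view looks
straight down; a ground point at altitude ``h`` projects to normalized
view coordinates ``u = x / (h * tan(fov_x/2))`` (and likewise v), both
in [-1, 1] across the sensor.  Lens distortion is applied in normalized
coordinates as a 6-term quadratic map per axis — the same polynomial
family the correction model fits, applied in the forward direction.  A
true radial pincushion is a cubic map and has no exact representative
in this family, so ``pincushion_strength`` generates a quadratic
caricature (a corner-bending cross term); the fitted correction is then
an approximation of the map's true inverse, as it is for a real lens.
Annotated endpoints are rounded to integer pixels by default, which is
the pixel-quantization error source that drives the small negative bias
the ground-truth calibration corrects.

Population and survey.  Shell heights follow a truncated Gaussian
mixture (default bimodal with the large mode dominant, as expected for
a long-lived, lightly recruited stock); shells arrive as a Poisson
process at a fixed density per square meter of imaged seabed (default
1/m^2).  The survey hierarchy mirrors the field design: 5 repeated
surveys of 4 transects, 25 frames sampled per transect, with altitude
and pitch/roll jitter per frame.  Between-group variability is injected
as additive Gaussian survey/transect/frame effects on log-height
(multiplicative on height, keeping heights positive; for the small
sigmas used this is indistinguishable from the additive model the
analysis fits).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import GridCorrespondence, quadratic_design_matrix
from .errors import InvalidGeometryError

__all__ = [
    "TrueCameraModel",
    "PopulationSpec",
    "SurveyPlan",
    "generate_calibration_grid",
    "generate_survey_data",
    "generate_ground_truth_experiment",
    "simulate_nested_heights",
    "render_frame_image",
]


@dataclass(frozen=True)
class TrueCameraModel:
    """Downward pinhole camera with a quadratic forward distortion.

    ``forward_coeffs_u``/``forward_coeffs_v`` map undistorted normalized
    view coordinates (u, v) to distorted ones in the 6-term basis
    (1, u, v, u^2, v^2, u*v); identity is (0,1,0,0,0,0)/(0,0,1,0,0,0).
    """

    image_width_px: int = 1024
    image_height_px: int = 768
    fov_x_deg: float = 53.13   # footprint ~2.0 m across at 2 m altitude
    fov_y_deg: float = 33.40   # footprint ~1.2 m along at 2 m altitude
    forward_coeffs_u: np.ndarray = field(
        default_factory=lambda: np.array([0, 1, 0, 0, 0, 0], dtype=float)
    )
    forward_coeffs_v: np.ndarray = field(
        default_factory=lambda: np.array([0, 0, 1, 0, 0, 0], dtype=float)
    )
    pincushion_strength: float = 0.0

    def __post_init__(self) -> None:
        cu = np.asarray(self.forward_coeffs_u, dtype=float)
        cv = np.asarray(self.forward_coeffs_v, dtype=float)
        object.__setattr__(self, "forward_coeffs_u", cu)
        object.__setattr__(self, "forward_coeffs_v", cv)
        if cu.shape != (6,) or cv.shape != (6,):
            raise InvalidGeometryError("forward maps need 6 coefficients")
        if self.image_width_px < 1 or self.image_height_px < 1:
            raise InvalidGeometryError("pixel counts must be >= 1")

    @classmethod
    def with_pincushion(cls, strength: float = 0.02, **kwargs) -> "TrueCameraModel":
        """Camera whose corners are displaced by ~``strength`` of the
        half-sensor extent (quadratic cross-term caricature of
        pincushion distortion; lines bend, more strongly toward the
        corners)."""
        return cls(
            forward_coeffs_u=np.array([0, 1, 0, 0, 0, strength], dtype=float),
            forward_coeffs_v=np.array([0, 0, 1, 0, 0, strength], dtype=float),
            pincushion_strength=strength,
            **kwargs,
        )

    # -- geometry -----------------------------------------------------
    def footprint_m(self, altitude_m: float) -> tuple[float, float]:
        """(across, along) ground footprint in meters at ``altitude_m``."""
        if altitude_m <= 0:
            raise InvalidGeometryError("altitude must be > 0")
        return (
            2.0 * altitude_m * math.tan(math.radians(self.fov_x_deg) / 2.0),
            2.0 * altitude_m * math.tan(math.radians(self.fov_y_deg) / 2.0),
        )

    def ground_sample_distance_cm(self, altitude_m: float) -> tuple[float, float]:
        fx, fy = self.footprint_m(altitude_m)
        return (
            fx * 100.0 / self.image_width_px,
            fy * 100.0 / self.image_height_px,
        )

    def _distort(self, u: np.ndarray, v: np.ndarray):
        X = quadratic_design_matrix(u, v)
        return X @ self.forward_coeffs_u, X @ self.forward_coeffs_v

    def project_ground(
        self, points_m: np.ndarray, altitude_m: float
    ) -> np.ndarray:
        """Project ground points (meters from nadir, x across/east-ish,
        y along, y increasing downward in the image) to distorted pixel
        coordinates at the given altitude."""
        pts = np.atleast_2d(np.asarray(points_m, dtype=float))
        hx = altitude_m * math.tan(math.radians(self.fov_x_deg) / 2.0)
        hy = altitude_m * math.tan(math.radians(self.fov_y_deg) / 2.0)
        u, v = pts[:, 0] / hx, pts[:, 1] / hy
        ud, vd = self._distort(u, v)
        return np.column_stack(
            [
                self.image_width_px / 2.0 + ud * self.image_width_px / 2.0,
                self.image_height_px / 2.0 + vd * self.image_height_px / 2.0,
            ]
        )

    def check_injective(self, margin: float = 1.05, n: int = 41) -> bool:
        """Numerically verify the forward map is orientation-preserving
        (positive Jacobian determinant) over the sensor extent."""
        g = np.linspace(-margin, margin, n)
        u, v = np.meshgrid(g, g)
        u, v = u.ravel(), v.ravel()
        cu, cv = self.forward_coeffs_u, self.forward_coeffs_v
        du_du = cu[1] + 2 * cu[3] * u + cu[5] * v
        du_dv = cu[2] + 2 * cu[4] * v + cu[5] * u
        dv_du = cv[1] + 2 * cv[3] * u + cv[5] * v
        dv_dv = cv[2] + 2 * cv[4] * v + cv[5] * u
        det = du_du * dv_dv - du_dv * dv_du
        return bool(np.all(det > 0))


@dataclass(frozen=True)
class PopulationSpec:
    """Seabed scallop population: spatial density and size structure."""

    density_per_m2: float = 1.0
    mixture_weights: tuple[float, ...] = (0.35, 0.65)
    mixture_means_cm: tuple[float, ...] = (4.5, 7.0)
    mixture_sds_cm: tuple[float, ...] = (0.8, 0.9)
    live_fraction: float = 0.85

    def __post_init__(self) -> None:
        w = np.asarray(self.mixture_weights, dtype=float)
        if abs(w.sum() - 1.0) > 1e-9 or np.any(w < 0):
            raise ValueError("mixture weights must be >= 0 and sum to 1")
        if np.any(np.asarray(self.mixture_sds_cm) <= 0):
            raise ValueError("mixture sds must be > 0")
        if self.density_per_m2 < 0:
            raise ValueError("density must be >= 0")
        if not 0 <= self.live_fraction <= 1:
            raise ValueError("live_fraction must be in [0, 1]")

    def sample_heights(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n heights (cm) from the mixture, truncated at > 0."""
        out = np.empty(n)
        todo = np.arange(n)
        while todo.size:
            comp = rng.choice(
                len(self.mixture_weights), size=todo.size,
                p=self.mixture_weights,
            )
            draw = rng.normal(
                np.asarray(self.mixture_means_cm)[comp],
                np.asarray(self.mixture_sds_cm)[comp],
            )
            out[todo] = draw
            todo = todo[draw <= 0]
        return out


@dataclass(frozen=True)
class SurveyPlan:
    """Hierarchical survey design and vehicle-attitude jitter."""

    n_surveys: int = 5
    transects_per_survey: int = 4
    frames_per_transect_available: int = 60
    frames_sampled: int = 25
    altitude_mean_m: float = 2.0
    altitude_sd_m: float = 0.35
    pitch_sd_deg: float = 1.0
    roll_sd_deg: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_surveys, self.transects_per_survey,
               self.frames_per_transect_available, self.frames_sampled) < 1:
            raise ValueError("counts must be positive")
        if min(self.altitude_sd_m, self.pitch_sd_deg, self.roll_sd_deg) < 0:
            raise ValueError("jitter sds must be >= 0")


def generate_calibration_grid(
    camera: TrueCameraModel,
    spacing_cm: float = 15.0,
    h_frame_m: float = 2.0,
    noise_sd_px: float = 0.0,
    seed: int | np.random.Generator = 0,
    n_cols: int | None = None,
    n_rows: int | None = None,
) -> GridCorrespondence:
    """Photograph a checkerboard of ``spacing_cm`` squares at altitude
    ``h_frame_m`` through the camera's forward distortion.

    Reference points are the node positions in cm in the grid plane
    (origin at the optical center); distorted points are their projected
    pixel positions, optionally with Gaussian pixel noise.  Node counts
    default to as many as fit the footprint.
    """
    if spacing_cm <= 0:
        raise ValueError("spacing must be > 0")
    if not camera.check_injective():
        raise InvalidGeometryError(
            "camera forward distortion is not injective over the sensor"
        )
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    fx_m, fy_m = camera.footprint_m(h_frame_m)
    half_x_cm, half_y_cm = fx_m * 50.0, fy_m * 50.0

    def _axis_nodes(half_cm: float, n: int | None) -> np.ndarray:
        if n is None:
            n = int(math.floor(2 * 0.98 * half_cm / spacing_cm)) + 1
        return spacing_cm * (np.arange(n) - (n - 1) / 2.0)

    xs = _axis_nodes(half_x_cm, n_cols)
    ys = _axis_nodes(half_y_cm, n_rows)
    gx, gy = np.meshgrid(xs, ys)
    reference = np.column_stack([gx.ravel(), gy.ravel()])
    distorted = camera.project_ground(reference / 100.0, h_frame_m)
    if noise_sd_px > 0:
        distorted = distorted + rng.normal(0, noise_sd_px, distorted.shape)
    return GridCorrespondence(
        distorted_points=distorted,
        reference_points=reference,
        grid_spacing_cm=spacing_cm,
        frame_altitude_m=h_frame_m,
    )


def _truncated_normal(rng, mean, sd, lower, size=None):
    draw = rng.normal(mean, sd, size=size)
    bad = draw <= lower
    while np.any(bad):
        draw = np.where(bad, rng.normal(mean, sd, size=size), draw)
        bad = draw <= lower
    return draw


def generate_survey_data(
    pop: PopulationSpec,
    plan: SurveyPlan,
    camera: TrueCameraModel,
    h_frame_m: float = 2.0,
    sigma_survey: float = 0.0,
    sigma_transect: float = 0.01,
    sigma_frame: float = 0.03,
    quantize: bool = True,
    drop_partial: bool = False,
    seed: int | np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate one full repeated survey: metadata, annotations, truth.

    Per frame: altitude ~ truncated Normal, pitch/roll ~ Normal, shell
    count ~ Poisson(density x footprint area at that altitude); each
    shell gets a mixture height multiplied by exp(survey + transect +
    frame effect) (effects ~ Normal(0, sigma) on log-height), a uniform
    position and orientation, and its height-axis endpoints are
    projected through the forward distortion, then rounded to integer
    pixels if ``quantize``.  Shells whose endpoints leave the sensor are
    flagged ``partially_visible`` (or dropped when ``drop_partial``).

    Returns ``(metadata, annotations, truth)``; the truth table links
    every shell to its generating height and group effects.
    """
    if not camera.check_injective():
        raise InvalidGeometryError(
            "camera forward distortion is not injective over the sensor"
        )
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(plan.seed if seed is None else seed))
    meta_rows, ann_rows, truth_rows = [], [], []
    t0 = pd.Timestamp("2011-11-07 10:00:00")
    frame_counter = 0
    for si in range(plan.n_surveys):
        s_eff = rng.normal(0.0, sigma_survey) if sigma_survey > 0 else 0.0
        for ti in range(plan.transects_per_survey):
            t_eff = (rng.normal(0.0, sigma_transect)
                     if sigma_transect > 0 else 0.0)
            for fi in range(plan.frames_per_transect_available):
                f_eff = (rng.normal(0.0, sigma_frame)
                         if sigma_frame > 0 else 0.0)
                image_id = f"s{si + 1}_t{ti + 1}_f{fi + 1:03d}"
                altitude = float(_truncated_normal(
                    rng, plan.altitude_mean_m, plan.altitude_sd_m, 0.2
                ))
                pitch = float(rng.normal(0.0, plan.pitch_sd_deg))
                roll = float(rng.normal(0.0, plan.roll_sd_deg))
                fx_m, fy_m = camera.footprint_m(altitude)
                meta_rows.append(
                    {
                        "image_id": image_id,
                        "survey_id": f"s{si + 1}",
                        "transect_id": f"t{ti + 1}",
                        "timestamp": (
                            t0 + pd.Timedelta(seconds=frame_counter)
                        ).isoformat(),
                        "lat": 65.0933 + ti * 1e-4 + fi * 2e-6,
                        "lon": -22.7583 + si * 1e-4 + fi * 3e-6,
                        "altitude_m": altitude,
                        "depth_m": 30.0 - altitude + float(rng.normal(0, 0.3)),
                        "pitch_deg": pitch,
                        "roll_deg": roll,
                    }
                )
                frame_counter += 1
                n_shells = int(rng.poisson(pop.density_per_m2 * fx_m * fy_m))
                if n_shells == 0:
                    continue
                base_heights = pop.sample_heights(n_shells, rng)
                heights = base_heights * math.exp(s_eff + t_eff + f_eff)
                cx = rng.uniform(-fx_m / 2.0, fx_m / 2.0, n_shells)
                cy = rng.uniform(-fy_m / 2.0, fy_m / 2.0, n_shells)
                theta = rng.uniform(0.0, math.pi, n_shells)
                half_m = heights / 200.0  # cm -> m, half-span
                dx, dy = half_m * np.cos(theta), half_m * np.sin(theta)
                tips = camera.project_ground(
                    np.column_stack([cx + dx, cy + dy]), altitude
                )
                bases = camera.project_ground(
                    np.column_stack([cx - dx, cy - dy]), altitude
                )
                if quantize:
                    tips, bases = np.rint(tips), np.rint(bases)
                inside = (
                    (tips[:, 0] >= 0) & (tips[:, 0] <= camera.image_width_px)
                    & (tips[:, 1] >= 0)
                    & (tips[:, 1] <= camera.image_height_px)
                    & (bases[:, 0] >= 0)
                    & (bases[:, 0] <= camera.image_width_px)
                    & (bases[:, 1] >= 0)
                    & (bases[:, 1] <= camera.image_height_px)
                )
                alive = rng.random(n_shells) < pop.live_fraction
                for k in range(n_shells):
                    if drop_partial and not inside[k]:
                        continue
                    shell_id = f"{image_id}_sh{k + 1}"
                    ann_rows.append(
                        {
                            "shell_id": shell_id,
                            "image_id": image_id,
                            "tip_x_px": tips[k, 0],
                            "tip_y_px": tips[k, 1],
                            "base_x_px": bases[k, 0],
                            "base_y_px": bases[k, 1],
                            "status": "live" if alive[k] else "dead",
                            "partially_visible": not inside[k],
                        }
                    )
                    truth_rows.append(
                        {
                            "shell_id": shell_id,
                            "true_height_cm": heights[k],
                            "base_height_cm": base_heights[k],
                            "survey_effect": s_eff,
                            "transect_effect": t_eff,
                            "frame_effect": f_eff,
                        }
                    )
    metadata = pd.DataFrame(meta_rows)
    ann_cols = ["shell_id", "image_id", "tip_x_px", "tip_y_px",
                "base_x_px", "base_y_px", "status", "partially_visible"]
    truth_cols = ["shell_id", "true_height_cm", "base_height_cm",
                  "survey_effect", "transect_effect", "frame_effect"]
    annotations = (pd.DataFrame(ann_rows) if ann_rows
                   else pd.DataFrame(columns=ann_cols))
    truth = (pd.DataFrame(truth_rows) if truth_rows
             else pd.DataFrame(columns=truth_cols))
    return metadata, annotations, truth


def generate_ground_truth_experiment(
    camera: TrueCameraModel,
    category_means_cm: tuple[float, ...] = (5.5, 6.0, 6.5, 7.0),
    n_per_category: int = 25,
    within_category_sd_cm: float = 0.1,
    h_frame_m: float = 2.0,
    altitude_m: float = 2.0,
    quantize: bool = True,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Plant shells of known height flat on the bottom and photograph
    them through the same projection path as the survey.

    One image per size category; shells are placed in the central 80%
    of the footprint (never partially visible), with uniform random
    orientation.  Returns ``(annotations, metadata, known)`` where
    ``known`` has shell_id, category, known_height_cm.
    """
    if len(category_means_cm) < 2:
        raise ValueError(">= 2 size categories required")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    fx_m, fy_m = camera.footprint_m(altitude_m)
    ann_rows, meta_rows, known_rows = [], [], []
    for ci, mean in enumerate(category_means_cm):
        image_id = f"gt_c{ci + 1}"
        meta_rows.append(
            {
                "image_id": image_id,
                "survey_id": "groundtruth",
                "transect_id": f"c{ci + 1}",
                "timestamp": f"2011-11-01T12:{ci:02d}:00",
                "lat": 65.09, "lon": -22.76,
                "altitude_m": altitude_m,
                "depth_m": altitude_m,
                "pitch_deg": 0.0, "roll_deg": 0.0,
            }
        )
        heights = _truncated_normal(
            rng, mean, within_category_sd_cm, 0.0, size=n_per_category
        ) if within_category_sd_cm > 0 else np.full(n_per_category, mean)
        cx = rng.uniform(-0.4 * fx_m, 0.4 * fx_m, n_per_category)
        cy = rng.uniform(-0.4 * fy_m, 0.4 * fy_m, n_per_category)
        theta = rng.uniform(0.0, math.pi, n_per_category)
        half_m = heights / 200.0
        dx, dy = half_m * np.cos(theta), half_m * np.sin(theta)
        tips = camera.project_ground(
            np.column_stack([cx + dx, cy + dy]), altitude_m
        )
        bases = camera.project_ground(
            np.column_stack([cx - dx, cy - dy]), altitude_m
        )
        if quantize:
            tips, bases = np.rint(tips), np.rint(bases)
        for k in range(n_per_category):
            shell_id = f"{image_id}_sh{k + 1}"
            ann_rows.append(
                {
                    "shell_id": shell_id,
                    "image_id": image_id,
                    "tip_x_px": tips[k, 0],
                    "tip_y_px": tips[k, 1],
                    "base_x_px": bases[k, 0],
                    "base_y_px": bases[k, 1],
                    "status": "live",
                    "partially_visible": False,
                }
            )
            known_rows.append(
                {
                    "shell_id": shell_id,
                    "category": ci + 1,
                    "category_mean_cm": mean,
                    "known_height_cm": heights[k],
                }
            )
    return (
        pd.DataFrame(ann_rows),
        pd.DataFrame(meta_rows),
        pd.DataFrame(known_rows),
    )


def simulate_nested_heights(
    mu: float = 6.0,
    sigma2_survey: float = 0.0,
    sigma2_transect: float = 0.05,
    sigma2_frame: float = 0.3,
    sigma2_resid: float = 0.8,
    n_surveys: int = 5,
    transects_per_survey: int = 4,
    frames_per_transect: int = 25,
    obs_per_frame: int | float = 3,
    poisson_obs: bool = False,
    rng: np.random.Generator | int = 0,
) -> pd.DataFrame:
    """Draw heights directly from the additive nested Gaussian model.

    Used for variance-component recovery and null-calibration studies
    where the exact generating model of the analysis is wanted (no
    camera, no pixels).  With ``poisson_obs`` the per-frame count is
    Poisson(``obs_per_frame``) conditioned on >= 1.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    rows = []
    for si in range(n_surveys):
        s = rng.normal(0.0, math.sqrt(sigma2_survey)) if sigma2_survey else 0.0
        for ti in range(transects_per_survey):
            t = (rng.normal(0.0, math.sqrt(sigma2_transect))
                 if sigma2_transect else 0.0)
            for fi in range(frames_per_transect):
                f = (rng.normal(0.0, math.sqrt(sigma2_frame))
                     if sigma2_frame else 0.0)
                if poisson_obs:
                    n = 0
                    while n == 0:
                        n = int(rng.poisson(obs_per_frame))
                else:
                    n = int(obs_per_frame)
                e = rng.normal(0.0, math.sqrt(sigma2_resid), size=n)
                for y in mu + s + t + f + e:
                    rows.append(
                        {
                            "survey_id": f"s{si + 1}",
                            "transect_id": f"t{ti + 1}",
                            "frame_id": f"f{fi + 1}",
                            "height_cm": float(y),
                        }
                    )
    return pd.DataFrame(rows)


def render_frame_image(
    annotations: pd.DataFrame,
    camera: TrueCameraModel,
    path,
    background: int = 40,
    live_fill: int = 120,
    dead_fill: int = 230,
):
    """Write a schematic raster of one frame: an ellipse per shell whose
    major axis spans the annotated endpoints, brighter fill for dead
    shells.  Demo/visual-check output only; nothing downstream reads it.
    """
    from PIL import Image, ImageDraw

    img = Image.new(
        "L", (camera.image_width_px, camera.image_height_px), background
    )
    draw = ImageDraw.Draw(img)
    for _, row in annotations.iterrows():
        tip = np.array([row["tip_x_px"], row["tip_y_px"]], dtype=float)
        base = np.array([row["base_x_px"], row["base_y_px"]], dtype=float)
        center = (tip + base) / 2.0
        major = float(np.linalg.norm(tip - base)) / 2.0
        minor = 0.8 * major
        ang = math.atan2(tip[1] - base[1], tip[0] - base[0])
        ts = np.linspace(0.0, 2.0 * math.pi, 48)
        ex = major * np.cos(ts)
        ey = minor * np.sin(ts)
        xs = center[0] + ex * math.cos(ang) - ey * math.sin(ang)
        ys = center[1] + ex * math.sin(ang) + ey * math.cos(ang)
        fill = dead_fill if str(row["status"]).lower() == "dead" else live_fill
        draw.polygon(list(zip(xs.tolist(), ys.tolist())), fill=fill)
    img.save(path)
    return path
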