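"""Quadratic-polynomial lens-distortion correction.

Underwater camera lenses introduce geometric distortion (here a
pincushion effect, strongest toward the image corners).  Rather than
estimating a physical radial model, a flat checkerboard of known square
size photographed at a known altitude gives paired points: the distorted
pixel position of each grid node and its true position on the reference
grid (centimeters in the grid plane).  A second-order polynomial in the
distorted pixel coordinates,

    x_u = a0 + a1*x_d + a2*y_d + a3*x_d^2 + a4*y_d^2 + a5*x_d*y_d
    y_u = b0 + b1*x_d + b2*y_d + b3*x_d^2 + b4*y_d^2 + b5*x_d*y_d

is fitted per axis by ordinary least squares and maps any annotated
pixel point to undistorted physical coordinates in the grid plane.
Because the reference grid is in centimeters at the calibration
altitude, distances between corrected points are physical lengths there
and only the altitude ratio remains to scale a measurement made at a
different height (see :mod:`scallopsize.measurement`).

Pixel convention everywhere: origin at the top-left corner, x rightward,
y downward, 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
import yaml

from .errors import IncompatibilityError, UnderdeterminedFitError

__all__ = [
    "QUADRATIC_BASIS",
    "GridCorrespondence",
    "DistortionCorrectionModel",
    "quadratic_design_matrix",
    "fit_distortion_model",
    "undistort_point",
    "calibration_report",
    "save_model",
    "load_model",
]

#: Term order of the quadratic basis; coefficient vectors follow it.
QUADRATIC_BASIS = ("1", "x", "y", "x^2", "y^2", "x*y")


def quadratic_design_matrix(
    x: np.ndarray, y: np.ndarray, include_cross: bool = True
) -> np.ndarray:
    """Design matrix with columns (1, x, y, x^2, y^2, x*y).

    With ``include_cross=False`` the x*y column is zeroed (kept in place
    so coefficient vectors always have 6 entries in basis order).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cross = x * y if include_cross else np.zeros_like(x)
    return np.column_stack([np.ones_like(x), x, y, x * x, y * y, cross])


@dataclass(frozen=True)
class GridCorrespondence:
    """Paired distorted-pixel / reference-grid points from a calibration
    checkerboard.

    ``distorted_points`` are pixel coordinates of the grid nodes in the
    photograph; ``reference_points`` are their true positions in cm in
    the grid plane, photographed at altitude ``frame_altitude_m``.
    """

    distorted_points: np.ndarray  # (n, 2) pixels
    reference_points: np.ndarray  # (n, 2) cm in the grid plane
    grid_spacing_cm: float
    frame_altitude_m: float
    point_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        d = np.atleast_2d(np.asarray(self.distorted_points, dtype=float))
        r = np.atleast_2d(np.asarray(self.reference_points, dtype=float))
        object.__setattr__(self, "distorted_points", d)
        object.__setattr__(self, "reference_points", r)
        if d.shape != r.shape or d.ndim != 2 or d.shape[1] != 2:
            raise UnderdeterminedFitError(
                f"distorted {d.shape} and reference {r.shape} point arrays "
                "must be equal-shaped (n, 2)"
            )
        if len(d) < 6:
            raise UnderdeterminedFitError(
                f"need >= 6 correspondences for a 6-coefficient quadratic "
                f"model, got {len(d)}"
            )
        uniq = np.unique(d, axis=0)
        if len(uniq) != len(d):
            raise UnderdeterminedFitError("duplicated distorted points")
        if self.point_ids is None:
            object.__setattr__(self, "point_ids", np.arange(len(d)))

    @property
    def n_points(self) -> int:
        return len(self.distorted_points)


@dataclass(frozen=True)
class DistortionCorrectionModel:
    """Fitted per-axis quadratic correction (distorted px -> reference cm)."""

    coeffs_x: np.ndarray  # 6 coefficients in QUADRATIC_BASIS order
    coeffs_y: np.ndarray
    fit_rmse_x: float
    fit_rmse_y: float
    n_points: int
    frame_altitude_m: float
    include_cross: bool = True
    basis: tuple[str, ...] = field(default=QUADRATIC_BASIS)

    def __post_init__(self) -> None:
        cx = np.asarray(self.coeffs_x, dtype=float)
        cy = np.asarray(self.coeffs_y, dtype=float)
        object.__setattr__(self, "coeffs_x", cx)
        object.__setattr__(self, "coeffs_y", cy)
        if cx.shape != (6,) or cy.shape != (6,):
            raise ValueError("coefficient vectors must have exactly 6 entries")
        if not (np.all(np.isfinite(cx)) and np.all(np.isfinite(cy))):
            raise ValueError("coefficients must be finite")
        if self.fit_rmse_x < 0 or self.fit_rmse_y < 0:
            raise ValueError("fit RMSEs must be >= 0")

    def predict(self, points_px: np.ndarray) -> np.ndarray:
        """Map (n, 2) distorted pixel points to (n, 2) reference cm."""
        pts = np.atleast_2d(np.asarray(points_px, dtype=float))
        if not np.all(np.isfinite(pts)):
            raise ValueError("non-finite pixel coordinates")
        X = quadratic_design_matrix(pts[:, 0], pts[:, 1], True)
        return np.column_stack([X @ self.coeffs_x, X @ self.coeffs_y])

    @classmethod
    def identity(cls, frame_altitude_m: float = 1.0) -> "DistortionCorrectionModel":
        """Model mapping pixels to cm one-to-one (useful for tests/demos)."""
        return cls(
            coeffs_x=np.array([0, 1, 0, 0, 0, 0], dtype=float),
            coeffs_y=np.array([0, 0, 1, 0, 0, 0], dtype=float),
            fit_rmse_x=0.0,
            fit_rmse_y=0.0,
            n_points=0,
            frame_altitude_m=frame_altitude_m,
        )


def fit_distortion_model(
    grid: GridCorrespondence, include_cross: bool = True
) -> DistortionCorrectionModel:
    """Fit the per-axis quadratic correction by ordinary least squares.

    Each reference axis is regressed on the 6-term quadratic basis of the
    distorted pixel coordinates.  Raises
    :class:`~scallopsize.errors.UnderdeterminedFitError` when the design
    matrix is rank-deficient (e.g. collinear grid points).
    """
    xd, yd = grid.distorted_points[:, 0], grid.distorted_points[:, 1]
    X = quadratic_design_matrix(xd, yd, include_cross)
    needed = 6 if include_cross else 5
    cols = X if include_cross else X[:, :5]
    if np.linalg.matrix_rank(cols) < needed:
        raise UnderdeterminedFitError(
            "quadratic design matrix is rank-deficient; calibration points "
            "do not identify the model (collinear or too few distinct points)"
        )
    coeffs, rmses = [], []
    for axis in range(2):
        res = sm.OLS(grid.reference_points[:, axis], cols).fit()
        beta = np.zeros(6)
        beta[: cols.shape[1]] = res.params
        coeffs.append(beta)
        rmses.append(float(np.sqrt(np.mean(res.resid**2))))
    return DistortionCorrectionModel(
        coeffs_x=coeffs[0],
        coeffs_y=coeffs[1],
        fit_rmse_x=rmses[0],
        fit_rmse_y=rmses[1],
        n_points=grid.n_points,
        frame_altitude_m=grid.frame_altitude_m,
        include_cross=include_cross,
    )


def undistort_point(
    model: DistortionCorrectionModel, x_d: float, y_d: float
) -> tuple[float, float]:
    """Evaluate the correction polynomials at one distorted pixel point,
    returning reference-plane coordinates in cm."""
    out = model.predict(np.array([[x_d, y_d]]))
    return float(out[0, 0]), float(out[0, 1])


def calibration_report(
    model: DistortionCorrectionModel, grid: GridCorrespondence
) -> dict:
    """Residual summary of a fitted model against its calibration grid.

    Residuals are reference minus predicted, per point and axis; RMSE per
    axis matches the model's stored ``fit_rmse_*`` when the grid is the
    one the model was fitted from.
    """
    if model.n_points and model.n_points != grid.n_points:
        raise IncompatibilityError(
            f"model fitted from {model.n_points} points, grid has "
            f"{grid.n_points}"
        )
    predicted = model.predict(grid.distorted_points)
    residuals = grid.reference_points - predicted
    return {
        "residuals_cm": residuals,
        "rmse_x_cm": float(np.sqrt(np.mean(residuals[:, 0] ** 2))),
        "rmse_y_cm": float(np.sqrt(np.mean(residuals[:, 1] ** 2))),
        "max_abs_x_cm": float(np.max(np.abs(residuals[:, 0]))),
        "max_abs_y_cm": float(np.max(np.abs(residuals[:, 1]))),
        "n_points": grid.n_points,
    }


def save_model(model: DistortionCorrectionModel, path) -> None:
    """Serialize a correction model to a structured text (YAML) file."""
    payload = {
        "basis": list(model.basis),
        "coeffs_x": [float(c) for c in model.coeffs_x],
        "coeffs_y": [float(c) for c in model.coeffs_y],
        "fit_rmse_x_cm": float(model.fit_rmse_x),
        "fit_rmse_y_cm": float(model.fit_rmse_y),
        "n_points": int(model.n_points),
        "frame_altitude_m": float(model.frame_altitude_m),
        "include_cross": bool(model.include_cross),
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_model(path) -> DistortionCorrectionModel:
    with open(path, encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    return DistortionCorrectionModel(
        coeffs_x=np.array(payload["coeffs_x"], dtype=float),
        coeffs_y=np.array(payload["coeffs_y"], dtype=float),
        fit_rmse_x=payload["fit_rmse_x_cm"],
        fit_rmse_y=payload["fit_rmse_y_cm"],
        n_points=payload["n_points"],
        frame_altitude_m=payload["frame_altitude_m"],
        include_cross=payload.get("include_cross", True),
    )
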