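"""Bundle-shape quantification: circle fitting and contour length.

A microtubule bundle is traced as an ordered list of points (conventionally
ten, the first and last at the spindle poles).  Its curvature is summarized
by the radius of a least-squares circle through the trace — an algebraic
(Kasa) fit refined by geometric Gauss–Newton minimization of the orthogonal
residuals — and its length by the cumulative point-to-point distance.
Nearly-collinear traces are reported as an infinite-radius result rather
than a failure, since a straight bundle is a physically meaningful limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .core import DegenerateGeometryError, InvalidParameterError


@dataclass
class CircleFitResult:
    center: np.ndarray        # (2,) or (3,) µm; NaN for the collinear case
    radius: float             # µm; inf for collinear traces
    rms_residual: float       # µm
    contour_length: float     # µm
    is_collinear: bool = False


def _project_to_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Project 3D points onto their best-fit (total least squares) plane.

    Returns (2D coordinates, plane origin, 3x2 basis) so fitted centres can be
    lifted back to 3D.
    """
    centroid = points.mean(axis=0)
    rel = points - centroid
    _, _, vt = np.linalg.svd(rel, full_matrices=False)
    basis = vt[:2].T  # (3, 2)
    return rel @ basis, centroid, basis


def _kasa_fit(xy: np.ndarray) -> tuple[np.ndarray, float]:
    """Algebraic circle fit: linear least squares on x² + y² = 2ax + 2by + c."""
    x, y = xy[:, 0], xy[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x**2 + y**2
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:2]
    radius = float(np.sqrt(max(sol[2] + center @ center, 0.0)))
    return center, radius


def fit_circle(points, collinearity_tol: float = 1e-7,
               refine: bool = True) -> CircleFitResult:
    """Least-squares circle through an ordered bundle trace (2D or 3D points).

    3D traces are first projected onto their best-fit plane (traces are made
    on rotated 2D images, so out-of-plane scatter is noise).  The algebraic
    fit seeds a geometric refinement minimizing orthogonal distances; set
    ``refine=False`` for the purely algebraic result.  Traces whose transverse
    scatter is below ``collinearity_tol`` × span return radius = inf.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] not in (2, 3):
        raise InvalidParameterError("need >= 3 points of dimension 2 or 3")

    length = contour_length(pts)
    is3d = pts.shape[1] == 3
    if is3d:
        xy, origin, basis = _project_to_plane(pts)
    else:
        xy = pts

    # collinearity: transverse extent of the point cloud relative to its span
    rel = xy - xy.mean(axis=0)
    svals = np.linalg.svd(rel, compute_uv=False)
    span = svals[0]
    if span < 1e-15 or svals[1] / span < collinearity_tol:
        return CircleFitResult(
            center=np.full(pts.shape[1], np.nan),
            radius=np.inf,
            rms_residual=0.0,
            contour_length=length,
            is_collinear=True,
        )

    center, radius = _kasa_fit(xy)
    if refine:
        def residuals(params):
            cx, cy, r = params
            return np.hypot(xy[:, 0] - cx, xy[:, 1] - cy) - r

        sol = least_squares(residuals, x0=[center[0], center[1], radius], method="lm")
        center, radius = sol.x[:2], float(abs(sol.x[2]))
    res = np.hypot(xy[:, 0] - center[0], xy[:, 1] - center[1]) - radius
    rms = float(np.sqrt(np.mean(res**2)))
    if is3d:
        center_out = origin + basis @ center
    else:
        center_out = np.asarray(center, dtype=float)
    return CircleFitResult(
        center=center_out,
        radius=float(radius),
        rms_residual=rms,
        contour_length=length,
    )


def contour_length(points) -> float:
    """Cumulative distance along consecutive trace points, µm."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise InvalidParameterError("need >= 2 points")
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
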