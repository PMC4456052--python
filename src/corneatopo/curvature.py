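"""Per-column anterior radius of curvature by area-error circle fitting.

Fitting a circle by minimizing the squared *area* error

    J = sum_i [ pi R^2 - pi ((x_i - x_c)^2 + (y_i - y_c)^2) ]^2

is linear after the substitution B = R^2 - x_c^2 - y_c^2: the residual becomes
B + 2 x_c x_i + 2 y_c y_i - (x_i^2 + y_i^2), so the optimum solves a 3x3
normal system in closed form with no initial guess and no iteration — well
suited to processing an entire deformation sequence.  The fit carries the
known small-arc bias of algebraic circle fits (it slightly underestimates the
radius of shallow noisy arcs), which is acceptable at the arc lengths used
here (55-point windows on a ~490 px radius).

The per-column profile slides a window of ``half_width`` (default 27) pixels
on each side of the target column along the fitted anterior boundary, fits
the 2*half_width+1 points, and reports the signed radius in millimeters:
positive when the fitted center lies below the surface (convex toward the
camera), negative when above (concave, as at highest deformation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CircleFit", "CurvatureProfile", "circle_fit_area", "curvature_profile"]


@dataclass
class CircleFit:
    radius_px: float
    center_row: float
    center_col: float
    residual: float  # area-error objective J at the optimum
    n_points: int


@dataclass
class CurvatureProfile:
    radius_mm: np.ndarray  # signed radius per column (NaN where invalid)
    valid_cols: np.ndarray  # boolean
    half_width: int
    pixel_pitch: float


def circle_fit_area(points: np.ndarray) -> CircleFit:
    """Closed-form area-error circle fit of (row, col) points.

    Raises ``ValueError`` for degenerate input: fewer than 3 points, collinear
    points (singular normal matrix), or a non-positive squared radius.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (row, col) points")
    x = pts[:, 0]
    y = pts[:, 1]
    # shift to the centroid for conditioning; translation-equivariant fit
    x0, y0 = x.mean(), y.mean()
    xs, ys = x - x0, y - y0
    z = xs**2 + ys**2
    design = np.column_stack([np.ones_like(xs), xs, ys])
    lhs = design.T @ design
    rhs = design.T @ z
    try:
        sol = np.linalg.solve(lhs, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError("degenerate arc: collinear points") from exc
    cond = np.linalg.cond(lhs)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError("degenerate arc: collinear points")
    b, c1, c2 = sol
    xc, yc = c1 / 2.0, c2 / 2.0
    r_sq = b + xc**2 + yc**2
    if r_sq <= 0.0:
        raise ValueError("no real radius: non-positive R^2")
    radius = float(np.sqrt(r_sq))
    resid = float(np.sum((np.pi * r_sq - np.pi * ((xs - xc) ** 2 + (ys - yc) ** 2)) ** 2))
    return CircleFit(
        radius_px=radius,
        center_row=float(xc + x0),
        center_col=float(yc + y0),
        residual=resid,
        n_points=len(pts),
    )


def area_error(points: np.ndarray, radius: float, center: tuple[float, float]) -> float:
    """The area-error objective J for arbitrary circle parameters."""
    pts = np.asarray(points, dtype=float)
    d_sq = (pts[:, 0] - center[0]) ** 2 + (pts[:, 1] - center[1]) ** 2
    return float(np.sum((np.pi * radius**2 - np.pi * d_sq) ** 2))


def curvature_profile(
    boundary_rows: np.ndarray,
    half_width: int = 27,
    pixel_pitch: float = 0.016,
    valid: np.ndarray | None = None,
) -> CurvatureProfile:
    """Sliding-window signed radius along a per-column boundary curve.

    Columns whose window does not fit inside the valid range, or whose window
    is degenerate (straight boundary), are flagged invalid.
    """
    rows = np.asarray(boundary_rows, dtype=float)
    n_cols = rows.size
    if valid is None:
        valid = np.isfinite(rows)
    valid = np.asarray(valid, dtype=bool) & np.isfinite(rows)

    radius_mm = np.full(n_cols, np.nan)
    ok = np.zeros(n_cols, dtype=bool)
    cols = np.arange(n_cols, dtype=float)
    for j in range(half_width, n_cols - half_width):
        window = slice(j - half_width, j + half_width + 1)
        if not valid[window].all():
            continue
        pts = np.column_stack([rows[window], cols[window]])
        try:
            fit = circle_fit_area(pts)
        except ValueError:
            continue
        sign = 1.0 if fit.center_row > rows[j] else -1.0
        radius_mm[j] = sign * fit.radius_px * pixel_pitch
        ok[j] = True
    return CurvatureProfile(
        radius_mm=radius_mm, valid_cols=ok, half_width=half_width, pixel_pitch=pixel_pitch
    )
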