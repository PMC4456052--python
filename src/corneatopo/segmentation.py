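"""Corneal boundary tracing from phase maps with positional priors.

The cornea divides naturally into an upper (anterior) and lower (posterior)
surface around a bright center line.  The center line is traced first on the
phase-symmetry map: per column, the rows whose symmetry exceeds a threshold
(default 0.1) form a set L_j whose median is the raw center point; a degree-5
polynomial least-squares fit smooths the raw points (the symmetry intensity at
the raw point can serve as the fit weight).  Boundary points are then read off
the phase-asymmetry map: in each column, the supra-threshold response with the
largest row above the fitted center is the anterior candidate and the smallest
row below it the posterior candidate; each boundary is smoothed with the same
degree-5 fit.  Responses fade toward the image ends, so the outer columns are
flagged as low-confidence and accuracy claims are restricted to the central
two-thirds of the image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation, gaussian_filter

from . import phase, preprocess
from .config import PipelineConfig, SegmentationConfig

__all__ = [
    "CenterLine",
    "SegmentationResult",
    "center_line",
    "boundary_points",
    "fit_boundary",
    "segment",
]


@dataclass
class CenterLine:
    raw_rows: np.ndarray  # median row per valid column (NaN where invalid)
    raw_intensity: np.ndarray  # symmetry value at the raw point
    poly_coeffs: np.ndarray  # degree-5 polynomial, ascending powers
    fitted_rows: np.ndarray  # polynomial evaluated at every column
    valid_cols: np.ndarray  # boolean, columns with non-empty L_j


@dataclass
class SegmentationResult:
    center: CenterLine
    upper_rows: np.ndarray  # fitted anterior boundary, every column
    lower_rows: np.ndarray  # fitted posterior boundary
    upper_valid: np.ndarray  # columns that contributed an anterior candidate
    lower_valid: np.ndarray
    quality_flags: np.ndarray  # True where low-signal (outer image ends)

    @property
    def jointly_valid(self) -> np.ndarray:
        return self.upper_valid & self.lower_valid & self.center.valid_cols


def _lower_median(values: np.ndarray) -> float:
    """Median that stays on an actual pixel row for even-sized sets."""
    values = np.sort(values)
    return float(values[(len(values) - 1) // 2])


def _polyfit(
    cols: np.ndarray, rows: np.ndarray, degree: int, weights: np.ndarray | None = None
) -> np.ndarray:
    if cols.size < degree + 1:
        raise ValueError(
            f"insufficient support for degree-{degree} fit: "
            f"{cols.size} columns < {degree + 1}"
        )
    # center/scale the abscissa for conditioning; store plain coefficients
    series = np.polynomial.Polynomial.fit(cols, rows, deg=degree, w=weights)
    return series.convert().coef


def center_line(
    sym: np.ndarray,
    mask: preprocess.BinaryMask | np.ndarray,
    tau: float = 0.1,
    degree: int = 5,
    weight_fit: bool = True,
) -> CenterLine:
    """Trace the corneal midline on the symmetry map.

    L_j collects the rows of column j where ``sym > tau`` inside the mask; the
    raw center point is (lower-median(L_j), j) and carries the symmetry value
    at that pixel as its intensity.
    """
    sym = np.asarray(sym, dtype=float)
    mask_arr = np.asarray(mask, dtype=bool)
    n_cols = sym.shape[1]
    raw = np.full(n_cols, np.nan)
    inten = np.full(n_cols, np.nan)
    supra = (sym > tau) & mask_arr
    for j in range(n_cols):
        lj = np.flatnonzero(supra[:, j])
        if lj.size:
            r = _lower_median(lj)
            raw[j] = r
            inten[j] = sym[int(r), j]
    valid = ~np.isnan(raw)
    cols = np.flatnonzero(valid)
    weights = inten[valid] if weight_fit else None
    coeffs = _polyfit(cols, raw[valid], degree, weights)
    fitted = np.polynomial.polynomial.polyval(np.arange(n_cols, dtype=float), coeffs)
    return CenterLine(raw, inten, coeffs, fitted, valid)


def boundary_points(
    asym: np.ndarray,
    center: CenterLine,
    tau: float = 0.1,
    band_halfwidth: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-column anterior/posterior candidates from the asymmetry map.

    Per column and per side of the center line, the candidate is the bright
    supra-threshold asymmetry pixel closest to the center, where "bright"
    means within a factor of the side's maximum response: the pure
    nearest-to-center rule is fooled by weak odd-dominant responses inside
    the band, and the pure brightest rule by eyelashes attached above it.
    The search can additionally be restricted to ``center +/-
    band_halfwidth`` rows.  Returns (upper_rows, upper_valid, lower_rows,
    lower_valid).
    """
    asym = np.asarray(asym, dtype=float)
    n_rows, n_cols = asym.shape
    upper = np.full(n_cols, np.nan)
    lower = np.full(n_cols, np.nan)
    supra = asym > tau
    # a bright point is a local maximum of the column profile; gate it at a
    # fraction of its side's strongest peak
    interior = asym[1:-1]
    is_peak = np.zeros_like(supra)
    is_peak[1:-1] = (interior >= asym[:-2]) & (interior >= asym[2:]) & supra[1:-1]
    rel_gate = 0.5

    def _pick(rows: np.ndarray, j: int, nearest_idx: int) -> float:
        vals = asym[rows, j]
        bright = rows[vals >= rel_gate * vals.max()]
        return float(bright[nearest_idx])

    for j in range(n_cols):
        # the raw median center tracks sharp deformation better than the
        # quintic fit; use it to anchor the search window where available
        c = center.raw_rows[j] if center.valid_cols[j] else center.fitted_rows[j]
        rows = np.flatnonzero(is_peak[:, j])
        if band_halfwidth is not None:
            rows = rows[np.abs(rows - c) <= band_halfwidth]
        above = rows[rows < c]
        below = rows[rows > c]
        if above.size:
            upper[j] = _pick(above, j, -1)  # largest row = nearest from above
        if below.size:
            lower[j] = _pick(below, j, 0)  # smallest row = nearest from below
    return upper, ~np.isnan(upper), lower, ~np.isnan(lower)


def fit_boundary(
    cols: np.ndarray,
    rows: np.ndarray,
    n_cols: int,
    degree: int = 5,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Degree-5 polynomial smoothing of boundary candidates.

    Returns (fitted_rows over all columns, coefficients).
    """
    coeffs = _polyfit(np.asarray(cols, float), np.asarray(rows, float), degree, weights)
    fitted = np.polynomial.polynomial.polyval(np.arange(n_cols, dtype=float), coeffs)
    return fitted, coeffs


def _band_thickness(mask_arr: np.ndarray) -> float:
    """Median per-column foreground extent — the expected band thickness."""
    counts = mask_arr.sum(axis=0)
    counts = counts[counts > 0]
    if counts.size == 0:
        raise ValueError("empty mask")
    return float(np.median(counts))


def segment(frame: np.ndarray, config: PipelineConfig | None = None) -> SegmentationResult:
    """Full single-frame segmentation: artifacts -> phase maps -> boundaries."""
    config = config or PipelineConfig()
    seg_cfg: SegmentationConfig = config.segmentation

    mask = preprocess.cornea_mask(frame, config.preprocess)
    # feathered masking: a hard zero-cut at the mask border would add a
    # spurious step edge right next to the corneal boundary and bias the
    # fine-scale odd responses; dilate and blur so the transition is smooth
    # and sits away from the band
    soft = gaussian_filter(
        binary_dilation(mask.data, np.ones((3, 3), bool), iterations=6).astype(float),
        sigma=3.0,
    )
    clean = np.asarray(frame, dtype=float) * soft
    maps = phase.phase_maps(clean, config.phase)

    center = center_line(
        maps.sym,
        mask,
        tau=seg_cfg.tau_sym,
        degree=seg_cfg.poly_degree,
        weight_fit=seg_cfg.weight_center_fit,
    )
    halfwidth = seg_cfg.band_search_factor * _band_thickness(mask.data)
    up_raw, up_valid, lo_raw, lo_valid = boundary_points(
        maps.asym, center, tau=seg_cfg.tau_asym, band_halfwidth=halfwidth
    )
    n_cols = frame.shape[1]
    upper, _ = fit_boundary(
        np.flatnonzero(up_valid), up_raw[up_valid], n_cols, seg_cfg.poly_degree
    )
    lower, _ = fit_boundary(
        np.flatnonzero(lo_valid), lo_raw[lo_valid], n_cols, seg_cfg.poly_degree
    )

    n_flag = int(round(seg_cfg.end_flag_fraction * n_cols))
    flags = np.zeros(n_cols, dtype=bool)
    if n_flag:
        flags[:n_flag] = True
        flags[-n_flag:] = True
    return SegmentationResult(center, upper, lower, up_valid, lo_valid, flags)
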