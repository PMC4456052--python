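"""Evaluation quantities: central corneal thickness, deformation amplitude,
peak distance, and agreement statistics (Bland-Altman, Pearson r).

CCT is the anterior-to-posterior boundary separation at the central column,
converted to mm with the pixel pitch.  The highest-concavity frame maximizes
the apex displacement; at that frame the anterior surface shows two forward
bulges ("apexes") flanking the central depression, and the peak distance (PD)
is the Euclidean distance between them.  Bland-Altman agreement reports the
mean paired difference with mean +/- 2 SD limits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import pearsonr

from .segmentation import SegmentationResult

__all__ = [
    "FrameMetrics",
    "BlandAltman",
    "cct",
    "central_column",
    "deformation_amplitude",
    "highest_concavity",
    "peak_distance",
    "bland_altman",
    "pearson_r",
    "label_stages",
]


@dataclass
class FrameMetrics:
    cct_mm: float
    apex_row: float
    deformation_amplitude_mm: float
    pd_mm: float | None
    stage: str


@dataclass
class BlandAltman:
    mean_diff: float
    lower_limit: float
    upper_limit: float
    fraction_outside: float


def central_column(valid: np.ndarray) -> int:
    """Valid column closest to the image midline."""
    cols = np.flatnonzero(valid)
    if cols.size == 0:
        raise ValueError("no valid columns")
    mid = (len(valid) - 1) / 2.0
    return int(cols[np.argmin(np.abs(cols - mid))])


def cct(seg: SegmentationResult, pixel_pitch: float = 0.016) -> float:
    """Central corneal thickness in mm."""
    j = central_column(seg.jointly_valid)
    thickness_px = seg.lower_rows[j] - seg.upper_rows[j]
    if thickness_px <= 0:
        raise ValueError("non-positive thickness at the central column")
    return float(thickness_px * pixel_pitch)


def deformation_amplitude(
    seg: SegmentationResult, reference: SegmentationResult, pixel_pitch: float = 0.016
) -> float:
    """Apex displacement (mm) of the anterior boundary vs the reference frame."""
    j = central_column(seg.upper_valid & reference.upper_valid)
    return float((seg.upper_rows[j] - reference.upper_rows[j]) * pixel_pitch)


def highest_concavity(amplitudes_mm: np.ndarray) -> int:
    """Frame index of maximal deformation amplitude (earliest on ties)."""
    amplitudes_mm = np.asarray(amplitudes_mm, dtype=float)
    if amplitudes_mm.size < 3:
        raise ValueError("need at least 3 frames")
    return int(np.argmax(amplitudes_mm))


def peak_distance(
    seg: SegmentationResult,
    pixel_pitch: float = 0.016,
    prominence_px: float = 1.0,
) -> float:
    """Distance (mm) between the two forward apexes flanking the depression.

    Found as the two most prominent local minima of the fitted anterior
    boundary (forward bulge = smaller row); a concave central depression
    separates them, since consecutive local minima bracket a local maximum.
    Raises if the boundary shows no such pair (convex/monotone boundary).
    """
    rows = seg.upper_rows
    minima, props = find_peaks(-rows, prominence=prominence_px)
    if minima.size < 2:
        raise ValueError("PD undefined: anterior boundary shows no central concavity")
    top2 = minima[np.sort(np.argsort(props["prominences"])[-2:])]
    jl, jr = int(top2[0]), int(top2[1])
    d_px = float(np.hypot(rows[jr] - rows[jl], jr - jl))
    return d_px * pixel_pitch


def bland_altman(a: np.ndarray, b: np.ndarray) -> BlandAltman:
    """Agreement of two paired series: mean difference and +/- 2 SD limits."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("series must be paired with length >= 2")
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    lower, upper = mean - 2.0 * sd, mean + 2.0 * sd
    outside = float(np.mean((d < lower) | (d > upper)))
    return BlandAltman(mean, lower, upper, outside)


def pearson_r(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("series must be paired with length >= 3")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance")
    return float(pearsonr(a, b).statistic)


def label_stages(amplitudes_mm: np.ndarray, threshold_mm: float = 0.05) -> list[str]:
    """before/during/after by displacement thresholding."""
    amplitudes_mm = np.asarray(amplitudes_mm, dtype=float)
    during = amplitudes_mm >= threshold_mm
    labels = []
    peak = int(np.argmax(amplitudes_mm))
    for t, flag in enumerate(during):
        if flag:
            labels.append("during")
        else:
            labels.append("before" if t <= peak else "after")
    return labels
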