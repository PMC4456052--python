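"""Synthetic air-puff Scheimpflug frame generator with exact ground truth.

Emulates the appearance of a Corvis ST acquisition: a bright, near-horizontal
corneal band (anterior + posterior surface) on a dark background, corrupted by
uneven left-right illumination, additive Gaussian noise, and thin bright
eyelash/tear strokes above (optionally touching) the band.  A 140-frame
sequence follows the air-puff time course: the apex moves inward, passes
through a concave phase of highest deformation, and rebounds.

Geometry is analytic throughout.  The rest anterior surface is a circular arc
of configurable radius; the deformation adds a Gaussian-in-column indentation
whose amplitude follows a raised-cosine pulse in time.  Ground truth
(boundary rows, signed per-column radius of curvature, thickness, flanking
apex positions) is computed from the closed-form boundary function and is
exact for the noise-free geometry.

Coordinate convention: 0-based, row index increases downward, column index
increases rightward; boundary curves are functions row(column).  The signed
radius is positive where the anterior surface is convex toward the camera
(osculating-circle center at larger row than the surface) and negative where
concave.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from pydantic import Field
from scipy.special import ndtr

from .config import _StrictModel

__all__ = [
    "SyntheticConfig",
    "Artifact",
    "GroundTruth",
    "make_frame",
    "make_sequence",
    "random_artifacts",
    "displacement_profile",
    "stage_of",
]


class Artifact(_StrictModel):
    """A thin bright quadratic-Bezier stroke emulating an eyelash or tear film.

    Control points are (row, col) pairs; ``width`` is the stroke thickness in
    pixels and ``intensity`` the peak brightness added to the frame.
    """

    p0: tuple[float, float]
    p1: tuple[float, float]
    p2: tuple[float, float]
    width: float = Field(3.0, ge=1.0)
    intensity: float = Field(0.7, gt=0.0, le=1.0)


class SyntheticConfig(_StrictModel):
    n_rows: int = Field(200, gt=0)
    n_cols: int = Field(576, gt=0)
    pixel_pitch: float = Field(0.016, gt=0.0)  # mm per pixel
    n_frames: int = Field(140, gt=0)
    anterior_radius_mm: float = 7.8  # signed radius of the rest anterior arc
    cct_mm: float = Field(0.55, gt=0.0)  # central corneal thickness
    apex_row: float = 60.0  # rest-frame row of the anterior apex
    band_sigma: float = Field(3.0, gt=0.0)  # Gaussian edge width of the band (px)
    band_peak: float = Field(0.85, gt=0.0, le=1.0)
    illum_gradient: tuple[float, float] = (0.7, 1.0)
    noise_sigma: float = Field(0.02, ge=0.0)
    artifact_spec: list[Artifact] = Field(default_factory=list)
    deform_amplitude_mm: float = Field(1.0, ge=0.0)  # peak apex displacement
    deform_sigma_cols: float = Field(100.0, gt=0.0)  # column width of indentation
    concavity_frame: int = Field(70, ge=0)
    pulse_half_width: int = Field(35, gt=0)  # frames from pulse onset to peak
    seed: int = 0


@dataclass
class GroundTruth:
    """Exact noise-free geometry of one synthetic frame."""

    upper_rows: np.ndarray  # anterior boundary, real-valued row per column
    lower_rows: np.ndarray  # posterior boundary
    center_rows: np.ndarray  # midline
    radius_mm: np.ndarray  # signed per-column anterior radius (mm)
    cct_px: float  # central thickness in pixels
    apex_positions: tuple[int, int] | None  # flanking apex columns when concave
    artifact_mask: np.ndarray | None = None  # support of rendered artifacts
    stage: str = "before"  # before | during | after
    displacement_px: float = 0.0  # apex displacement at this frame
    artifact_components: list[np.ndarray] = field(default_factory=list)


def displacement_profile(config: SyntheticConfig, t: int) -> float:
    """Apex displacement (px, downward) at frame ``t``: raised-cosine pulse.

    Zero outside ``concavity_frame +/- pulse_half_width``, unimodal with its
    maximum exactly at ``concavity_frame``.
    """
    amp_px = config.deform_amplitude_mm / config.pixel_pitch
    u = (t - config.concavity_frame) / config.pulse_half_width
    if abs(u) >= 1.0:
        return 0.0
    return float(amp_px * 0.5 * (1.0 + np.cos(np.pi * u)))


def stage_of(config: SyntheticConfig, t: int) -> str:
    """Stage label by displacement thresholding (before/during/after)."""
    thr = 0.05 / config.pixel_pitch  # 0.05 mm expressed in px
    d = displacement_profile(config, t)
    if d >= thr:
        return "during"
    return "before" if t <= config.concavity_frame else "after"


def _boundary_functions(config: SyntheticConfig, t: int):
    """Closed-form anterior boundary r(j) and its first two derivatives."""
    r_px = config.anterior_radius_mm / config.pixel_pitch
    jc = (config.n_cols - 1) / 2.0
    d = displacement_profile(config, t)
    w = config.deform_sigma_cols

    half_span = jc
    if r_px <= half_span:
        raise ValueError(
            "anterior_radius_mm too small: arc half-span "
            f"{half_span:.1f} px exceeds radius {r_px:.1f} px"
        )

    def f(j):
        x = np.asarray(j, dtype=float) - jc
        s = np.sqrt(r_px**2 - x**2)
        g = np.exp(-(x**2) / (2.0 * w**2))
        return config.apex_row + (r_px - s) + d * g

    def fp(j):
        x = np.asarray(j, dtype=float) - jc
        s = np.sqrt(r_px**2 - x**2)
        g = np.exp(-(x**2) / (2.0 * w**2))
        return x / s - d * x / w**2 * g

    def fpp(j):
        x = np.asarray(j, dtype=float) - jc
        s = np.sqrt(r_px**2 - x**2)
        g = np.exp(-(x**2) / (2.0 * w**2))
        return r_px**2 / s**3 + d * (x**2 / w**4 - 1.0 / w**2) * g

    return f, fp, fpp


def _signed_radius_mm(config: SyntheticConfig, t: int, cols: np.ndarray) -> np.ndarray:
    f, fp, fpp = _boundary_functions(config, t)
    num = (1.0 + fp(cols) ** 2) ** 1.5
    den = fpp(cols)
    with np.errstate(divide="ignore"):
        radius_px = np.where(den != 0.0, num / den, np.inf)
    return radius_px * config.pixel_pitch


def _apex_positions(config: SyntheticConfig, t: int) -> tuple[int, int] | None:
    """Columns of the two forward bulges flanking a concave central depression.

    The indented boundary f(j) = arc(j) + d*gauss(j) has two interior local
    minima iff the central second derivative is negative; they are located by
    evaluating f on the integer grid.
    """
    f, _, fpp = _boundary_functions(config, t)
    jc = (config.n_cols - 1) / 2.0
    if fpp(np.array([jc]))[0] >= 0.0:
        return None
    cols = np.arange(config.n_cols)
    rows = f(cols)
    center = int(round(jc))
    left = cols[:center]
    right = cols[center + 1 :]
    if left.size == 0 or right.size == 0:
        return None
    return int(left[np.argmin(rows[:center])]), int(right[np.argmin(rows[center + 1 :])])


def _render_artifact(canvas: np.ndarray, art: Artifact) -> np.ndarray:
    """Stamp a quadratic Bezier stroke onto ``canvas``; return its support mask."""
    n_rows, n_cols = canvas.shape
    p0, p1, p2 = (np.asarray(p, dtype=float) for p in (art.p0, art.p1, art.p2))
    # arc length is bounded by control-polygon length; sample densely
    n_samp = int(4 * (np.linalg.norm(p1 - p0) + np.linalg.norm(p2 - p1))) + 8
    s = np.linspace(0.0, 1.0, n_samp)[:, None]
    pts = (1 - s) ** 2 * p0 + 2 * s * (1 - s) * p1 + s**2 * p2
    mask = np.zeros_like(canvas, dtype=bool)
    half = max(1, int(round(art.width / 2.0)))
    for r, c in pts:
        r0, r1 = int(round(r)) - half + 1, int(round(r)) + half
        c0, c1 = int(round(c)) - half + 1, int(round(c)) + half
        r0, c0 = max(r0, 0), max(c0, 0)
        r1, c1 = min(r1, n_rows), min(c1, n_cols)
        if r0 < r1 and c0 < c1:
            mask[r0:r1, c0:c1] = True
    canvas[mask] = np.maximum(canvas[mask], art.intensity)
    return mask


def random_artifacts(
    n: int,
    config: SyntheticConfig,
    rng: np.random.Generator,
    attached: bool = False,
) -> list[Artifact]:
    """Draw ``n`` eyelash-like strokes above the band.

    With ``attached=True`` one endpoint is placed on the anterior boundary so
    the stroke touches the corneal band (the hard case for area filtering).
    Strokes are kept laterally separated so they model distinct eyelashes;
    overlapping strokes would merge under closing into a single large object,
    which is a different (clumped-debris) scenario than this helper emulates.
    """
    f, _, _ = _boundary_functions(config, 0)
    arts: list[Artifact] = []
    placed: list[float] = []
    min_sep = 80.0  # columns between stroke anchors
    for _ in range(n):
        c0 = rng.uniform(0.1, 0.9) * config.n_cols
        for _try in range(50):
            if all(abs(c0 - p) >= min_sep for p in placed):
                break
            c0 = rng.uniform(0.1, 0.9) * config.n_cols
        placed.append(c0)
        upper = float(f(np.array([c0]))[0])
        if attached:
            r0 = upper + 1.0
        else:
            r0 = rng.uniform(5.0, max(6.0, upper - 15.0))
        length = rng.uniform(30.0, 80.0)
        angle = rng.uniform(-0.5, 0.5) - np.pi / 2  # roughly upward
        p2 = (r0 + length * np.sin(angle), c0 + length * np.cos(angle))
        bow = rng.uniform(-10.0, 10.0)
        p1 = ((r0 + p2[0]) / 2 + bow, (c0 + p2[1]) / 2 + bow)
        arts.append(
            Artifact(
                p0=(r0, c0),
                p1=p1,
                p2=p2,
                width=float(rng.uniform(2.0, 4.0)),
                intensity=float(rng.uniform(0.5, 0.9)),
            )
        )
    return arts


def make_frame(config: SyntheticConfig, t: int) -> tuple[np.ndarray, GroundTruth]:
    """Render frame ``t`` of the deformation sequence with its ground truth.

    The band has a flat top with Gaussian-CDF edges located exactly at the
    anterior/posterior boundary curves, so the per-column intensity argmax of
    the clean band sits on the midline and the steepest gradients sit on the
    boundaries.  Illumination gradient, artifacts and noise are applied on
    top; ground truth describes the noise-free geometry.
    """
    if not 0 <= t < config.n_frames:
        raise ValueError(f"frame index {t} outside [0, {config.n_frames})")

    cct_px = config.cct_mm / config.pixel_pitch
    cols = np.arange(config.n_cols)
    f, _, _ = _boundary_functions(config, t)
    upper = f(cols)
    lower = upper + cct_px
    center = upper + cct_px / 2.0

    margin = 2.0 * config.band_sigma
    if upper.min() - margin < 0:
        raise ValueError(
            f"band exceeds top of image (apex_row={config.apex_row}); "
            "increase apex_row or n_rows"
        )
    if lower.max() + margin > config.n_rows - 1:
        raise ValueError(
            f"band exceeds bottom of image (cct_mm={config.cct_mm}, "
            f"deform_amplitude_mm={config.deform_amplitude_mm}); increase n_rows"
        )

    rows = np.arange(config.n_rows, dtype=float)[:, None]
    # flat-top band: product of two Gaussian CDF edges at the two boundaries
    band = ndtr((rows - upper[None, :]) / config.band_sigma) * ndtr(
        (lower[None, :] - rows) / config.band_sigma
    )
    frame = config.band_peak * band

    lo, hi = config.illum_gradient
    frame *= np.linspace(lo, hi, config.n_cols)[None, :]

    artifact_mask = np.zeros_like(frame, dtype=bool)
    components: list[np.ndarray] = []
    for art in config.artifact_spec:
        m = _render_artifact(frame, art)
        components.append(m)
        artifact_mask |= m

    if config.noise_sigma > 0:
        rng = np.random.default_rng([config.seed, t])
        frame = frame + rng.normal(0.0, config.noise_sigma, frame.shape)
    frame = np.clip(frame, 0.0, 1.0)

    gt = GroundTruth(
        upper_rows=upper,
        lower_rows=lower,
        center_rows=center,
        radius_mm=_signed_radius_mm(config, t, cols),
        cct_px=float(cct_px),
        apex_positions=_apex_positions(config, t),
        artifact_mask=artifact_mask if components else None,
        stage=stage_of(config, t),
        displacement_px=displacement_profile(config, t),
        artifact_components=components,
    )
    return frame, gt


def make_sequence(
    config: SyntheticConfig,
) -> tuple[np.ndarray, list[GroundTruth]]:
    """Render the full deformation sequence as an (n_frames, rows, cols) array."""
    frames = np.empty((config.n_frames, config.n_rows, config.n_cols))
    truths: list[GroundTruth] = []
    for t in range(config.n_frames):
        frames[t], gt = make_frame(config, t)
        truths.append(gt)
    return frames, truths
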