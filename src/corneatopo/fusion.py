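"""Curvature topography rendering: radius normalization, pseudo-coloring and
CIECAM02 lightness/hue/saturation fusion.

The signed radius R (mm) is mapped to [0, 1] by a fixed piecewise-linear
normalization whose steep central branch (7 < R <= 10 mm, the physiological
anterior-radius range) spends most of the color gamut where discrimination
matters, while the long concave (negative) and flat (large positive) tails
are compressed:

    R_new = 0                         for R <= -35
          = 0.009 (R + 35)            for -35 < R <= 7
          = 0.1333 (R - 7) + 0.3761   for  7 < R <= 10
          = 0.009 (R - 10) + 0.7761   for 10 < R <= 35
          = 1                         for R > 35

The map is applied with identical constants to every frame of a sequence so
colors are comparable across the deformation stages.  The small branch-
junction offsets of the published constants (e.g. 0.378 vs 0.3761 at R = 7)
are kept verbatim; a continuous variant is available by configuration.

R_new selects a color from a fixed blue-to-red rainbow table; a strip of
configurable odd width (default 21 px) centered on the anterior boundary is
cut from the gray frame, and each strip pixel takes its lightness J from the
gray value and its hue quadrature H and saturation s from the pseudo-color,
via the forward/inverse CIECAM02 transforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from matplotlib.colors import hsv_to_rgb

from .ciecam02 import CAM02
from .config import FusionConfig
from .curvature import CurvatureProfile
from .segmentation import SegmentationResult

__all__ = [
    "RAINBOW_TABLE",
    "normalize_radius",
    "pseudo_color",
    "srgb_to_cam",
    "cam_to_srgb",
    "fuse_strip",
    "render_frame",
    "render_video",
    "colorbar_image",
]

# published breakpoints and slopes of the radius normalization
_BREAKS = (-35.0, 7.0, 10.0, 35.0)
_SLOPES = (0.009, 0.1333, 0.009)
_OFFSETS = (0.3761, 0.7761)


def _rainbow_table(n: int = 256) -> np.ndarray:
    """Blue-to-red rainbow: hue 240 deg -> 0 deg at full saturation/value."""
    hue = np.linspace(240.0, 0.0, n) / 360.0
    hsv = np.stack([hue, np.ones(n), np.ones(n)], axis=-1)
    return hsv_to_rgb(hsv)


RAINBOW_TABLE = _rainbow_table()


def normalize_radius(radius_mm, continuous: bool = False) -> np.ndarray:
    """Piecewise normalization of the signed radius into [0, 1].

    ``continuous=True`` rescales the two outer linear branches so the
    junctions meet exactly (removing the ~1e-3 offsets of the published
    constants); the default keeps the printed constants verbatim.
    """
    r = np.asarray(radius_mm, dtype=float)
    if not np.all(np.isfinite(r)):
        raise ValueError("non-finite radius")
    b0, b1, b2, b3 = _BREAKS
    if continuous:
        mid_lo = _SLOPES[0] * (b1 - b0)  # value reached at R = 7
        mid_hi = mid_lo + _SLOPES[1] * (b2 - b1)
        out = np.select(
            [r <= b0, r <= b1, r <= b2, r <= b3],
            [
                0.0,
                _SLOPES[0] * (r - b0),
                mid_lo + _SLOPES[1] * (r - b1),
                mid_hi + (1.0 - mid_hi) / (b3 - b2) * (r - b2),
            ],
            default=1.0,
        )
    else:
        out = np.select(
            [r <= b0, r <= b1, r <= b2, r <= b3],
            [
                0.0,
                _SLOPES[0] * (r + 35.0),
                _SLOPES[1] * (r - 7.0) + _OFFSETS[0],
                _SLOPES[0] * (r - 10.0) + _OFFSETS[1],
            ],
            default=1.0,
        )
    return np.clip(out, 0.0, 1.0)


def pseudo_color(rnew) -> np.ndarray:
    """Map normalized values to sRGB via the shipped rainbow table (linear
    interpolation between table entries)."""
    v = np.asarray(rnew, dtype=float)
    if np.any(v < 0.0) or np.any(v > 1.0):
        warnings.warn("normalized radius outside [0, 1]; clamping", stacklevel=2)
        v = np.clip(v, 0.0, 1.0)
    pos = v * (len(RAINBOW_TABLE) - 1)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, len(RAINBOW_TABLE) - 1)
    frac = (pos - lo)[..., None]
    return (1.0 - frac) * RAINBOW_TABLE[lo] + frac * RAINBOW_TABLE[hi]


def srgb_to_cam(rgb: np.ndarray, cfg: FusionConfig | None = None):
    """sRGB -> (J, H, s) under the configured viewing conditions."""
    cfg = cfg or FusionConfig()
    app = CAM02(cfg.viewing_conditions).srgb_forward(rgb)
    chroma = app.C if cfg.use_chroma else app.s
    return app.J, app.H, chroma


def cam_to_srgb(J, H, s, cfg: FusionConfig | None = None, return_clip_fraction=False):
    """(J, H, s) -> sRGB, clipped to gamut."""
    cfg = cfg or FusionConfig()
    cam = CAM02(cfg.viewing_conditions)
    if cfg.use_chroma:
        # convert chroma back to the saturation correlate expected by inverse
        Q = (4.0 / cam.c) * np.sqrt(np.asarray(J) / 100.0) * (cam.A_w + 4.0) * cam.F_L**0.25
        M = np.asarray(s) * cam.F_L**0.25
        with np.errstate(divide="ignore", invalid="ignore"):
            s = np.nan_to_num(100.0 * np.sqrt(M / np.where(Q == 0, 1.0, Q)))
    return cam.srgb_inverse(J, H, s, return_clip_fraction=return_clip_fraction)


def fuse_strip(
    gray_strip: np.ndarray,
    color_strip: np.ndarray,
    cfg: FusionConfig | None = None,
    return_clip_fraction: bool = False,
):
    """Merge gray lightness with pseudo-color hue/saturation per pixel."""
    cfg = cfg or FusionConfig()
    gray_strip = np.asarray(gray_strip, dtype=float)
    color_strip = np.asarray(color_strip, dtype=float)
    if gray_strip.shape != color_strip.shape[:-1]:
        raise ValueError(
            f"shape mismatch: gray {gray_strip.shape} vs color {color_strip.shape[:-1]}"
        )
    gray_rgb = np.repeat(gray_strip[..., None], 3, axis=-1)
    J_gray, _, _ = srgb_to_cam(gray_rgb, cfg)
    _, H_col, s_col = srgb_to_cam(color_strip, cfg)
    return cam_to_srgb(J_gray, H_col, s_col, cfg, return_clip_fraction=return_clip_fraction)


@dataclass
class RenderedFrame:
    image: np.ndarray  # (rows, cols, 3) sRGB in [0, 1]
    clip_fraction: float  # fraction of strip pixels clipped at the gamut


def render_frame(
    frame: np.ndarray,
    seg: SegmentationResult,
    prof: CurvatureProfile,
    cfg: FusionConfig | None = None,
) -> RenderedFrame:
    """Overlay the fused curvature strip on an RGB copy of the frame.

    The strip is ``strip_width`` rows centered on the (rounded) anterior
    boundary; the one-dimensional normalized-radius profile is copied down
    the strip width.  Columns without a valid radius stay gray.
    """
    cfg = cfg or FusionConfig()
    frame = np.asarray(frame, dtype=float)
    n_rows, n_cols = frame.shape
    half = cfg.strip_width // 2
    out = np.repeat(frame[..., None], 3, axis=-1)

    valid = prof.valid_cols & np.isfinite(seg.upper_rows)
    cols = np.flatnonzero(valid)
    if cols.size == 0:
        return RenderedFrame(out, 0.0)

    rnew = normalize_radius(
        prof.radius_mm[cols], continuous=cfg.continuous_normalization
    )
    color_line = pseudo_color(rnew)  # (n_valid, 3)

    centers = np.round(seg.upper_rows[cols]).astype(int)
    if (centers - half < 0).any() or (centers + half >= n_rows).any():
        warnings.warn("fusion strip truncated at the frame border", stacklevel=2)

    # gather strip pixels (clipped at borders), fuse in one vectorized call
    offsets = np.arange(-half, half + 1)
    strip_rows = np.clip(centers[None, :] + offsets[:, None], 0, n_rows - 1)
    gray_strip = frame[strip_rows, cols[None, :]]  # (width, n_valid)
    color_strip = np.broadcast_to(
        color_line[None, :, :], (cfg.strip_width, cols.size, 3)
    )
    fused, clip_frac = fuse_strip(gray_strip, color_strip, cfg, return_clip_fraction=True)
    out[strip_rows, cols[None, :]] = fused
    return RenderedFrame(out, clip_frac)


def colorbar_image(height: int = 24, width: int = 256) -> np.ndarray:
    """The shared color legend: normalized radius 0..1 left to right."""
    ramp = pseudo_color(np.linspace(0.0, 1.0, width))
    return np.broadcast_to(ramp[None, :, :], (height, width, 3)).copy()


def render_video(
    frames: np.ndarray,
    segs: list[SegmentationResult],
    profs: list[CurvatureProfile],
    cfg: FusionConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render every frame with the shared palette/normalization.

    Returns (rendered (T, rows, cols, 3) array, colorbar image); writing to
    disk is handled by the I/O layer.
    """
    cfg = cfg or FusionConfig()
    if not (len(frames) == len(segs) == len(profs)):
        raise ValueError("frames, segmentations and profiles must align")
    rendered = np.stack(
        [render_frame(f, s, p, cfg).image for f, s, p in zip(frames, segs, profs)]
    )
    return rendered, colorbar_image()
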