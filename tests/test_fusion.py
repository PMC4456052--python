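"""Radius normalization, rainbow palette, and CIECAM02 strip fusion."""


import numpy as np
import pytest

from corneatopo import fusion
from corneatopo.ciecam02 import CAM02
from corneatopo.config import FusionConfig
from corneatopo.curvature import CurvatureProfile
from corneatopo.fusion import (
    cam_to_srgb,
    colorbar_image,
    fuse_strip,
    normalize_radius,
    pseudo_color,
    render_frame,
    render_video,
    srgb_to_cam,
)


@pytest.mark.parametrize(
    "radius, expected",
    [
        (-40.0, 0.0),  # deep concave branch
        (-35.0, 0.0),  # breakpoint belongs to the flat branch
        (0.0, 0.315),  # 0.009 * 35
        (7.0, 0.378),  # second branch at its upper end: 0.009 * 42
        (np.nextafter(7.0, np.inf), 0.3761),  # third branch lower limit
        (10.0, 0.3761 + 0.1333 * 3.0),
        (100.0, 1.0),
    ],
)
def test_normalize_radius_branch_values(radius, expected):
    assert normalize_radius(radius) == pytest.approx(expected, abs=1e-9)


def test_normalize_radius_monotone_and_bounded():
    """Non-decreasing within branch interiors and within [0, 1] on a dense
    grid; the published constants give small upward jumps at the junctions,
    which are kept verbatim."""
    r = np.linspace(-60.0, 60.0, 100_001)
    out = normalize_radius(r)
    assert out.min() >= 0.0 and out.max() <= 1.0
    diffs = np.diff(out)
    # exclude steps that straddle a published branch junction: the printed
    # constants step DOWN by 0.0019 across R=7 (0.378 -> 0.3761)
    junction = np.zeros(len(diffs), dtype=bool)
    for b in (-35.0, 7.0, 10.0, 35.0):
        junction |= (r[:-1] <= b) & (r[1:] > b)
    assert np.all(diffs[~junction] >= -1e-12)
    # and the continuous variant is globally non-decreasing
    cont = normalize_radius(r, continuous=True)
    assert np.all(np.diff(cont) >= -1e-12)


def test_normalize_radius_junction_offsets_preserved():
    """The printed constants are discontinuous: 0.378 vs 0.3761 at R=7."""
    below = normalize_radius(7.0)
    above = normalize_radius(np.nextafter(7.0, np.inf))
    assert below == pytest.approx(0.378, abs=1e-9)
    assert above == pytest.approx(0.3761, abs=1e-9)
    # continuous variant removes the jump
    c_below = normalize_radius(7.0, continuous=True)
    c_above = normalize_radius(np.nextafter(7.0, np.inf), continuous=True)
    assert abs(c_above - c_below) < 1e-6


def test_normalize_radius_rejects_nonfinite():
    with pytest.raises(ValueError, match="finite"):
        normalize_radius(np.array([1.0, np.nan]))


def test_palette_endpoints_and_hue_monotonicity():
    assert np.allclose(pseudo_color(0.0), [0.0, 0.0, 1.0], atol=1e-12)  # blue
    assert np.allclose(pseudo_color(1.0), [1.0, 0.0, 0.0], atol=1e-12)  # red
    from matplotlib.colors import rgb_to_hsv

    hues = rgb_to_hsv(fusion.RAINBOW_TABLE)[:, 0]
    assert np.all(np.diff(hues) < 0)  # 240 deg -> 0 deg, strictly monotone


def test_pseudo_color_clamps_with_warning():
    with pytest.warns(UserWarning, match="clamping"):
        out = pseudo_color(np.array([-0.2, 1.3]))
    assert np.allclose(out[0], [0.0, 0.0, 1.0])
    assert np.allclose(out[1], [1.0, 0.0, 0.0])


def test_fuse_uniform_strip_preserves_lightness():
    gray = np.full((5, 8), 0.55)
    color = np.broadcast_to(pseudo_color(0.5), (5, 8, 3))
    fused = fuse_strip(gray, color)
    cam = CAM02(FusionConfig().viewing_conditions)
    J_out = cam.srgb_forward(fused).J
    J_in = cam.srgb_forward(np.full((5, 8, 3), 0.55)).J
    assert np.max(np.abs(J_out - J_in)) <= 0.5
    # uniform inputs give a uniform output
    assert np.allclose(fused, fused[0, 0], atol=1e-9)


def test_fuse_black_strip_stays_black():
    gray = np.zeros((4, 6))
    color = np.broadcast_to(pseudo_color(0.9), (4, 6, 3))
    fused = fuse_strip(gray, color)
    assert np.allclose(fused, 0.0, atol=1.0 / 255.0)


def test_fuse_gradient_gray_keeps_hue_constant():
    gray = np.tile(np.linspace(0.2, 0.9, 16), (3, 1))
    color = np.broadcast_to(pseudo_color(0.25), (3, 16, 3))
    fused = fuse_strip(gray, color)
    cam = CAM02(FusionConfig().viewing_conditions)
    H = cam.srgb_forward(fused).H
    assert H.max() - H.min() <= 1.0


def test_fuse_shape_mismatch_errors():
    with pytest.raises(ValueError, match="shape"):
        fuse_strip(np.zeros((4, 6)), np.zeros((4, 7, 3)))


def test_srgb_cam_chroma_variant_roundtrip():
    cfg = FusionConfig(use_chroma=True)
    rng = np.random.default_rng(0)
    rgb = rng.uniform(0.1, 0.9, (50, 3))
    J, H, C = srgb_to_cam(rgb, cfg)
    back = cam_to_srgb(J, H, C, cfg)
    assert np.max(np.abs(back - rgb)) < 1.0 / 255.0


def _flat_profile(n, value=7.8):
    radius = np.full(n, value)
    valid = np.zeros(n, dtype=bool)
    valid[27:-27] = True
    radius[~valid] = np.nan
    return CurvatureProfile(radius, valid, 27, 0.016)


def test_render_frame_paste_contract(rest_frame, rest_segmentation):
    """Pixels outside the strip are untouched; invalid columns stay gray."""
    cfg, frame, _ = rest_frame
    seg, _ = rest_segmentation
    prof = _flat_profile(cfg.n_cols)
    rendered = render_frame(frame, seg, prof, FusionConfig())
    img = rendered.image
    half = FusionConfig().strip_width // 2
    strip = np.zeros(frame.shape, dtype=bool)
    for j in np.flatnonzero(prof.valid_cols):
        c = int(round(seg.upper_rows[j]))
        strip[max(0, c - half) : c + half + 1, j] = True
    gray3 = np.repeat(frame[..., None], 3, axis=-1)
    assert np.array_equal(img[~strip], gray3[~strip])
    # invalid columns (first 27) are bit-identical to the gray input
    assert np.array_equal(img[:, :27], gray3[:, :27])


def test_render_frame_constant_radius_single_hue(rest_frame, rest_segmentation):
    """A constant-radius profile renders as one hue band along the boundary."""
    cfg, frame, _ = rest_frame
    seg, _ = rest_segmentation
    prof = _flat_profile(cfg.n_cols)
    img = render_frame(frame, seg, prof, FusionConfig()).image
    cam = CAM02(FusionConfig().viewing_conditions)
    cols = np.flatnonzero(prof.valid_cols)[20:-20]
    rows = np.round(seg.upper_rows[cols]).astype(int)
    px = img[rows, cols]
    bright = px.max(axis=-1) > 0.2  # hue is meaningless on near-black pixels
    H = cam.srgb_forward(px[bright]).H
    assert H.max() - H.min() <= 1.0


def test_render_video_shared_palette(rest_frame, rest_segmentation):
    """Identical radii in different frames map to identical colors."""
    cfg, frame, _ = rest_frame
    seg, _ = rest_segmentation
    prof = _flat_profile(cfg.n_cols)
    frames = np.stack([frame, frame])
    rendered, colorbar = render_video(frames, [seg, seg], [prof, prof])
    assert rendered.shape == (2, cfg.n_rows, cfg.n_cols, 3)
    assert np.array_equal(rendered[0], rendered[1])
    assert colorbar.shape[2] == 3


def test_colorbar_spans_palette():
    bar = colorbar_image(height=8, width=64)
    assert np.allclose(bar[0, 0], [0.0, 0.0, 1.0], atol=1e-9)
    assert np.allclose(bar[0, -1], [1.0, 0.0, 0.0], atol=1e-9)
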