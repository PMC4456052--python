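"""Log-Gabor bank and phase symmetry/asymmetry maps.

The central check is the oracle equivalence: the vectorized maps must equal a
literal per-pixel/per-scale/per-orientation transcription of the defining
formulas on a small frame.
"""

import numpy as np
import pytest

from corneatopo import phase
from corneatopo.config import PhaseConfig


@pytest.fixture(scope="module")
def bank64():
    return phase.build_bank(PhaseConfig(), (64, 64))


def naive_phase_maps(resp: phase.FilterResponses, config: PhaseConfig):
    """Per-pixel loop transcription of the symmetry/asymmetry definitions."""
    n_s, n_o, rows, cols = resp.even.shape
    amp = resp.amplitude
    # same noise floors as the implementation; independence is in the
    # accumulation arithmetic, which is the part worth cross-checking
    T = phase._noise_thresholds(resp, config)
    sym = np.zeros((rows, cols))
    asym = np.zeros((rows, cols))
    for r in range(rows):
        for c in range(cols):
            num_s = num_a = den = 0.0
            for s in range(n_s):
                for o in range(n_o):
                    e = abs(resp.even[s, o, r, c])
                    od = abs(resp.odd[s, o, r, c])
                    num_s += max(e - od - T[s, o], 0.0)
                    num_a += max(od - e - T[s, o], 0.0)
                    den += amp[s, o, r, c]
            sym[r, c] = num_s / (den + config.epsilon)
            asym[r, c] = num_a / (den + config.epsilon)
    return sym, asym


def test_bank_has_no_dc_response(bank64):
    assert np.all(bank64.filters[:, :, 0, 0] == 0.0)


def test_bank_wavelength_progression():
    cfg = PhaseConfig(n_scales=3, min_wavelength=4, scale_multiplier=2.0)
    bank = phase.build_bank(cfg, (64, 64))
    assert np.allclose(bank.wavelengths, [4.0, 8.0, 16.0])


def test_bank_rejects_oversized_wavelength():
    with pytest.raises(ValueError, match="wavelength"):
        phase.build_bank(PhaseConfig(min_wavelength=40.0), (32, 32))


def test_white_noise_scale_amplitudes(bank64):
    """Per-scale amplitude medians on white noise are positive and fall with
    scale (log-Gabor energy grows with center frequency at constant relative
    bandwidth); Monte-Carlo over seeded realizations."""
    rng = np.random.default_rng(0)
    meds = np.zeros((4, PhaseConfig().n_scales))
    for k in range(4):
        resp = phase.responses(rng.normal(size=(64, 64)), bank64)
        meds[k] = np.median(resp.amplitude, axis=(1, 2, 3))
    mean_meds = meds.mean(axis=0)
    assert np.all(mean_meds > 0)
    assert np.all(np.diff(mean_meds) < 0)


def test_constant_frame_gives_zero_responses(bank64):
    resp = phase.responses(np.full((64, 64), 0.37), bank64)
    assert np.allclose(resp.even, 0.0, atol=1e-12)
    assert np.allclose(resp.odd, 0.0, atol=1e-12)


def test_amplitude_identity(bank64):
    rng = np.random.default_rng(1)
    resp = phase.responses(rng.random((64, 64)), bank64)
    assert np.allclose(
        resp.amplitude**2, resp.even**2 + resp.odd**2, atol=1e-9
    )


def test_ridge_is_even_dominant(bank64):
    """A delta ridge drives the even-symmetric responses; the aligned
    orientation shows |even| >> |odd| on the ridge row."""
    ridge = np.zeros((64, 64))
    ridge[32] = 1.0
    resp = phase.responses(ridge, bank64)
    o_aligned = PhaseConfig().n_orientations // 2  # horizontal structure
    e = np.abs(resp.even[:, o_aligned, 32, :]).mean()
    o = np.abs(resp.odd[:, o_aligned, 32, :]).mean()
    assert e > 10 * o


def test_step_edge_is_odd_dominant(bank64):
    step = np.zeros((64, 64))
    step[:, 32:] = 1.0
    resp = phase.responses(step, bank64)
    e = np.abs(resp.even[:, 0, :, 32]).mean()
    o = np.abs(resp.odd[:, 0, :, 32]).mean()
    assert o > 2 * e


def test_maps_zero_on_zero_responses():
    cfg = PhaseConfig()
    resp = phase.FilterResponses(
        even=np.zeros((2, 2, 8, 8)), odd=np.zeros((2, 2, 8, 8))
    )
    assert np.all(phase.phase_symmetry(resp, cfg) == 0.0)
    assert np.all(phase.phase_asymmetry(resp, cfg) == 0.0)


def test_maps_bounded(bank64):
    rng = np.random.default_rng(2)
    frame = rng.random((64, 64))
    maps = phase.phase_maps(frame, PhaseConfig())
    for m in (maps.sym, maps.asym):
        assert m.min() >= 0.0 and m.max() <= 1.0


def test_sym_peaks_on_ridge_line():
    ridge = np.zeros((64, 64))
    ridge[32] = 1.0
    maps = phase.phase_maps(ridge, PhaseConfig())
    rows = maps.sym.argmax(axis=0)
    assert np.all(rows == 32)


def test_asym_peaks_on_band_edges():
    """On a synthetic band, asymmetry attains its per-column local maxima at
    the two edges (+/- 1 px)."""
    frame = np.zeros((80, 64))
    frame[30:50] = 0.9
    maps = phase.phase_maps(frame, PhaseConfig())
    for j in range(10, 54):
        col = maps.asym[:, j]
        top = 20 + np.argmax(col[20:40])
        bot = 40 + np.argmax(col[40:60])
        assert abs(top - 29.5) <= 1.5  # edge between rows 29 and 30
        assert abs(bot - 49.5) <= 1.5


def test_asym_vanishes_on_symmetry_axis(bank64):
    rows = np.arange(64, dtype=float)[:, None]
    frame = np.exp(-((rows - 31.5) ** 2) / (2 * 4.0**2)) * np.ones((1, 64))
    maps = phase.phase_maps(frame, PhaseConfig())
    axis = maps.asym[31:33, :]
    assert axis.max() < 0.05


def test_contrast_invariance_with_zero_noise_floor():
    """With T forced off (noise_k=0 and a bank-free frame), the maps are
    invariant to global intensity scaling up to epsilon effects."""
    cfg = PhaseConfig(noise_k=0.0, epsilon=1e-12)
    rng = np.random.default_rng(3)
    frame = rng.random((48, 48))
    m1 = phase.phase_maps(frame, cfg)
    m2 = phase.phase_maps(2.0 * frame, cfg)
    assert np.allclose(m1.sym, m2.sym, atol=1e-6)
    assert np.allclose(m1.asym, m2.asym, atol=1e-6)


def test_vectorized_equals_naive_loop():
    """Oracle equivalence on a 32x32 frame to 1e-10."""
    cfg = PhaseConfig(min_wavelength=3, scale_multiplier=1.8)
    rng = np.random.default_rng(4)
    frame = rng.random((32, 32))
    bank = phase.build_bank(cfg, frame.shape)
    resp = phase.responses(frame, bank)
    sym_ref, asym_ref = naive_phase_maps(resp, cfg)
    assert np.allclose(phase.phase_symmetry(resp, cfg), sym_ref, atol=1e-10)
    assert np.allclose(phase.phase_asymmetry(resp, cfg), asym_ref, atol=1e-10)


def test_nonfinite_frame_rejected(bank64):
    bad = np.zeros((64, 64))
    bad[0, 0] = np.nan
    with pytest.raises(ValueError, match="finite"):
        phase.responses(bad, bank64)
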