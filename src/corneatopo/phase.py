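"""Phase symmetry and asymmetry maps from a log-Gabor quadrature filter bank.

Local phase is a contrast-invariant cue: at a ridge (delta-like feature) all
frequency components sit at a peak or valley of their cycle, so the
even-symmetric filter outputs dominate; at a step edge the components sit at
inflection points and the odd-symmetric outputs dominate.  Per orientation and
scale the bank yields a quadrature pair (e_n, o_n) with amplitude
A_n = sqrt(e_n^2 + o_n^2); the symmetry map accumulates the clamped excess
max(|e_n| - |o_n| - T_n, 0) over scales and orientations and normalizes by the
total amplitude (plus a small epsilon), giving a value in [0, 1].  The
asymmetry map swaps the roles of |e_n| and |o_n|.

T_n is a scale-specific noise floor estimated from the amplitude distribution
of the smallest-scale (noisiest) filter, assuming Rayleigh-distributed noise
amplitudes, and propagated to coarser scales by the geometric bandwidth decay
of the bank.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft as _fft

from .config import PhaseConfig

__all__ = [
    "FilterBank",
    "FilterResponses",
    "PhaseMaps",
    "build_bank",
    "responses",
    "phase_symmetry",
    "phase_asymmetry",
    "phase_maps",
]


@dataclass
class FilterBank:
    """Frequency-domain log-Gabor filters, one per (scale, orientation)."""

    filters: np.ndarray  # (n_scales, n_orientations, rows, cols), real
    wavelengths: np.ndarray  # (n_scales,) center wavelengths in px
    config: PhaseConfig
    shape: tuple[int, int]


@dataclass
class FilterResponses:
    """Quadrature responses: even/odd/amplitude, (S, O, rows, cols)."""

    even: np.ndarray
    odd: np.ndarray

    @property
    def amplitude(self) -> np.ndarray:
        return np.hypot(self.even, self.odd)


@dataclass
class PhaseMaps:
    sym: np.ndarray
    asym: np.ndarray


def _lowpass(shape: tuple[int, int], cutoff: float = 0.45, order: int = 15) -> np.ndarray:
    """Butterworth low-pass on the FFT grid; tames the corner frequencies."""
    rows, cols = shape
    fy = np.fft.fftfreq(rows)[:, None]
    fx = np.fft.fftfreq(cols)[None, :]
    radius = np.hypot(fx, fy)
    return 1.0 / (1.0 + (radius / cutoff) ** (2 * order))


def build_bank(config: PhaseConfig, shape: tuple[int, int]) -> FilterBank:
    """Construct the log-Gabor bank in the frequency domain.

    Radial part: log-Gaussian around center frequency 1/wavelength_n with
    wavelength_n = min_wavelength * scale_multiplier**n; zero at DC.  Angular
    part: Gaussian in orientation over one half-plane, which makes the spatial
    filter a complex quadrature pair (real part even, imaginary part odd).
    """
    rows, cols = shape
    if rows <= 0 or cols <= 0:
        raise ValueError("shape must be positive")
    wavelengths = config.min_wavelength * config.scale_multiplier ** np.arange(
        config.n_scales
    )
    if wavelengths[-1] > max(rows, cols):
        raise ValueError(
            f"coarsest wavelength {wavelengths[-1]:.1f} px exceeds image size "
            f"{max(rows, cols)} px"
        )

    fy = np.fft.fftfreq(rows)[:, None]
    fx = np.fft.fftfreq(cols)[None, :]
    radius = np.hypot(fx, fy)
    radius[0, 0] = 1.0  # avoid log(0); the DC bin is zeroed below
    theta = np.arctan2(-fy, fx)  # orientation measured on the frequency plane
    sin_t, cos_t = np.sin(theta), np.cos(theta)

    lp = _lowpass(shape)
    log_sigma = np.log(config.sigma_on_f)
    bank = np.empty((config.n_scales, config.n_orientations, rows, cols))
    # orientation Gaussian std tied to the angular spacing so adjacent
    # orientations overlap smoothly
    sigma_theta = np.pi / config.n_orientations / 1.2
    for s, wl in enumerate(wavelengths):
        f0 = 1.0 / wl
        radial = np.exp(-(np.log(radius / f0) ** 2) / (2.0 * log_sigma**2)) * lp
        radial[0, 0] = 0.0
        for o in range(config.n_orientations):
            angle = o * np.pi / config.n_orientations
            ds = sin_t * np.cos(angle) - cos_t * np.sin(angle)
            dc = cos_t * np.cos(angle) + sin_t * np.sin(angle)
            dtheta = np.abs(np.arctan2(ds, dc))
            spread = np.exp(-(dtheta**2) / (2.0 * sigma_theta**2))
            bank[s, o] = radial * spread
    return FilterBank(filters=bank, wavelengths=wavelengths, config=config, shape=shape)


def responses(frame: np.ndarray, bank: FilterBank) -> FilterResponses:
    """Convolve the frame with every filter; even = real, odd = imaginary part."""
    frame = np.asarray(frame, dtype=float)
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite values")
    if frame.shape != bank.shape:
        raise ValueError(f"frame shape {frame.shape} != bank shape {bank.shape}")
    spectrum = _fft.fft2(frame)
    eo = _fft.ifft2(spectrum[None, None] * bank.filters, axes=(-2, -1))
    return FilterResponses(even=eo.real.copy(), odd=eo.imag.copy())


def _noise_thresholds(resp: FilterResponses, config: PhaseConfig) -> np.ndarray:
    """Per-(scale, orientation) noise floor T_n.

    The smallest-scale amplitude median estimates the Rayleigh scale of the
    noise response (median = tau * sqrt(ln 4)); the expected noise amplitude
    mean and spread follow from Rayleigh moments, and coarser scales inherit
    the estimate attenuated by the bank's geometric bandwidth decay.
    """
    amp = resp.amplitude
    n_scales = amp.shape[0]
    tau1 = np.median(amp[0], axis=(-2, -1)) / np.sqrt(np.log(4.0))  # (O,)
    decay = (1.0 / config.scale_multiplier) ** np.arange(n_scales)  # (S,)
    tau = tau1[None, :] * decay[:, None]  # (S, O)
    mean = tau * np.sqrt(np.pi / 2.0)
    sigma = tau * np.sqrt((4.0 - np.pi) / 2.0)
    return mean + config.noise_k * sigma


def _phase_map(resp: FilterResponses, config: PhaseConfig, kind: str) -> np.ndarray:
    abs_e = np.abs(resp.even)
    abs_o = np.abs(resp.odd)
    diff = abs_e - abs_o if kind == "sym" else abs_o - abs_e
    T = _noise_thresholds(resp, config)  # (S, O)
    numer = np.maximum(diff - T[:, :, None, None], 0.0).sum(axis=(0, 1))
    denom = resp.amplitude.sum(axis=(0, 1)) + config.epsilon
    return numer / denom


def phase_symmetry(resp: FilterResponses, config: PhaseConfig) -> np.ndarray:
    """Symmetry map in [0, 1]: ridges of either polarity light up."""
    return _phase_map(resp, config, "sym")


def phase_asymmetry(resp: FilterResponses, config: PhaseConfig) -> np.ndarray:
    """Asymmetry map in [0, 1]: step edges light up."""
    return _phase_map(resp, config, "asym")


_BANK_CACHE: dict[tuple, FilterBank] = {}


def _cached_bank(config: PhaseConfig, shape: tuple[int, int]) -> FilterBank:
    key = (tuple(sorted(config.model_dump().items())), shape)
    if key not in _BANK_CACHE:
        if len(_BANK_CACHE) > 8:  # bound memory across many shapes
            _BANK_CACHE.clear()
        _BANK_CACHE[key] = build_bank(config, shape)
    return _BANK_CACHE[key]


def phase_maps(frame: np.ndarray, config: PhaseConfig | None = None) -> PhaseMaps:
    """Convenience wrapper: bank + responses + both maps for one frame.

    The filter bank is cached per (config, shape) so sequences reuse it.
    """
    config = config or PhaseConfig()
    bank = _cached_bank(config, frame.shape)
    resp = responses(frame, bank)
    return PhaseMaps(
        sym=phase_symmetry(resp, config), asym=phase_asymmetry(resp, config)
    )
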