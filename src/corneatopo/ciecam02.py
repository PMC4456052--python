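"""CIECAM02 color appearance model: sRGB <-> (lightness J, hue quadrature H,
saturation s).

Implements the CIE 159:2004 forward and inverse transforms, vectorized over
arrays of colors.  The forward chain is sRGB -> linear RGB -> CIE XYZ (D65)
-> CAT02 chromatic adaptation -> Hunt-Pointer-Estevez space -> nonlinear
response compression -> opponent signals -> appearance correlates.  The
inverse chain recovers XYZ from (J, H, s) under the same viewing conditions
and returns sRGB, clipping out-of-gamut results to [0, 1].

Only the correlates needed for lightness/hue/saturation fusion are exposed;
chroma C is available as an alternative colorfulness correlate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ViewingConditions

__all__ = ["CAM02", "Appearance", "srgb_to_xyz", "xyz_to_srgb"]

_M_CAT02 = np.array(
    [
        [0.7328, 0.4296, -0.1624],
        [-0.7036, 1.6975, 0.0061],
        [0.0030, 0.0136, 0.9834],
    ]
)
_M_HPE = np.array(
    [
        [0.38971, 0.68898, -0.07868],
        [-0.22981, 1.18340, 0.04641],
        [0.00000, 0.00000, 1.00000],
    ]
)
_M_SRGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)

_SURROUNDS = {
    "average": (1.0, 0.69, 1.0),  # F, c, N_c
    "dim": (0.9, 0.59, 0.9),
    "dark": (0.8, 0.525, 0.8),
}

# unique hue data for the hue-quadrature interpolation
_HUE_H = np.array([20.14, 90.00, 164.25, 237.53, 380.14])
_HUE_E = np.array([0.8, 0.7, 1.0, 1.2, 0.8])
_HUE_Q = np.array([0.0, 100.0, 200.0, 300.0, 400.0])


def srgb_to_xyz(rgb: np.ndarray) -> np.ndarray:
    """sRGB in [0,1] (any shape ending in 3) to XYZ on the 0-100 scale."""
    rgb = np.asarray(rgb, dtype=float)
    lin = np.where(rgb <= 0.04045, rgb / 12.92, ((rgb + 0.055) / 1.055) ** 2.4)
    return 100.0 * lin @ _M_SRGB_TO_XYZ.T


def xyz_to_srgb(xyz: np.ndarray) -> np.ndarray:
    """XYZ (0-100 scale) to sRGB in [0,1]; values are NOT clipped here."""
    lin = (np.asarray(xyz, dtype=float) / 100.0) @ np.linalg.inv(_M_SRGB_TO_XYZ).T
    lin = np.clip(lin, 0.0, None)  # tiny negatives from rounding
    return np.where(lin <= 0.0031308, 12.92 * lin, 1.055 * lin ** (1 / 2.4) - 0.055)


@dataclass
class Appearance:
    J: np.ndarray  # lightness
    H: np.ndarray  # hue quadrature, [0, 400)
    s: np.ndarray  # saturation
    C: np.ndarray  # chroma
    h: np.ndarray  # hue angle, degrees


def _compress(x: np.ndarray, f_l: float) -> np.ndarray:
    """Post-adaptation nonlinear response compression (sign-preserving)."""
    t = (f_l * np.abs(x) / 100.0) ** 0.42
    return np.sign(x) * 400.0 * t / (27.13 + t) + 0.1


def _decompress(x: np.ndarray, f_l: float) -> np.ndarray:
    p = x - 0.1
    ap = np.abs(p)
    ap = np.minimum(ap, 400.0 - 1e-9)  # guard the pole
    return np.sign(p) * (100.0 / f_l) * (27.13 * ap / (400.0 - ap)) ** (1.0 / 0.42)


class CAM02:
    """CIECAM02 model bound to a set of viewing conditions."""

    def __init__(self, vc: ViewingConditions | None = None):
        vc = vc or ViewingConditions()
        self.vc = vc
        try:
            self.F, self.c, self.N_c = _SURROUNDS[vc.surround]
        except KeyError:
            raise ValueError(f"unknown surround {vc.surround!r}") from None
        self.xyz_w = np.asarray(vc.white_xyz, dtype=float)
        l_a = vc.adapting_luminance
        if vc.discount_illuminant:
            self.D = 1.0
        else:
            self.D = np.clip(
                self.F * (1.0 - (1.0 / 3.6) * np.exp(-(l_a + 42.0) / 92.0)), 0.0, 1.0
            )
        k = 1.0 / (5.0 * l_a + 1.0)
        self.F_L = 0.2 * k**4 * 5.0 * l_a + 0.1 * (1.0 - k**4) ** 2 * (5.0 * l_a) ** (
            1.0 / 3.0
        )
        self.n = vc.background_luminance / self.xyz_w[1]
        self.N_bb = self.N_cb = 0.725 * (1.0 / self.n) ** 0.2
        self.z = 1.48 + np.sqrt(self.n)

        rgb_w = _M_CAT02 @ self.xyz_w
        self.d_scale = self.xyz_w[1] * self.D / rgb_w + 1.0 - self.D
        rgb_wc = self.d_scale * rgb_w
        rgb_wp = _M_HPE @ np.linalg.inv(_M_CAT02) @ rgb_wc
        rgb_wa = _compress(rgb_wp, self.F_L)
        self.A_w = (2.0 * rgb_wa[0] + rgb_wa[1] + rgb_wa[2] / 20.0 - 0.305) * self.N_bb

    # ---------------------------------------------------------------- forward
    def forward(self, xyz: np.ndarray) -> Appearance:
        """XYZ (0-100) -> appearance correlates."""
        xyz = np.asarray(xyz, dtype=float)
        rgb = xyz @ _M_CAT02.T
        rgb_c = rgb * self.d_scale
        rgb_p = rgb_c @ (_M_HPE @ np.linalg.inv(_M_CAT02)).T
        rgb_a = _compress(rgb_p, self.F_L)

        ra, ga, ba = rgb_a[..., 0], rgb_a[..., 1], rgb_a[..., 2]
        a = ra - 12.0 * ga / 11.0 + ba / 11.0
        b = (ra + ga - 2.0 * ba) / 9.0
        h = np.degrees(np.arctan2(b, a)) % 360.0

        e_t = 0.25 * (np.cos(np.radians(h) + 2.0) + 3.8)
        A = (2.0 * ra + ga + ba / 20.0 - 0.305) * self.N_bb
        A = np.maximum(A, 0.0)
        J = 100.0 * (A / self.A_w) ** (self.c * self.z)

        denom = ra + ga + 21.0 * ba / 20.0
        t = (
            (50000.0 / 13.0)
            * self.N_c
            * self.N_cb
            * e_t
            * np.hypot(a, b)
            / np.where(denom == 0.0, 1e-300, denom)
        )
        C = t**0.9 * np.sqrt(J / 100.0) * (1.64 - 0.29**self.n) ** 0.73
        M = C * self.F_L**0.25
        Q = (4.0 / self.c) * np.sqrt(J / 100.0) * (self.A_w + 4.0) * self.F_L**0.25
        with np.errstate(divide="ignore", invalid="ignore"):
            s = 100.0 * np.sqrt(np.where(Q > 0.0, M / np.where(Q == 0, 1, Q), 0.0))
        s = np.nan_to_num(s)
        return Appearance(J=J, H=self._hue_quadrature(h), s=s, C=C, h=h)

    @staticmethod
    def _hue_quadrature(h: np.ndarray) -> np.ndarray:
        hp = np.where(h < _HUE_H[0], h + 360.0, h)
        i = np.searchsorted(_HUE_H, hp, side="right") - 1
        i = np.clip(i, 0, 3)
        num = (hp - _HUE_H[i]) / _HUE_E[i]
        den = num + (_HUE_H[i + 1] - hp) / _HUE_E[i + 1]
        return _HUE_Q[i] + 100.0 * num / np.where(den == 0.0, 1.0, den)

    @staticmethod
    def _hue_from_quadrature(H: np.ndarray) -> np.ndarray:
        H = np.asarray(H, dtype=float) % 400.0
        i = np.clip(np.searchsorted(_HUE_Q, H, side="right") - 1, 0, 3)
        dH = H - _HUE_Q[i]
        num = dH * (_HUE_E[i + 1] * _HUE_H[i] - _HUE_E[i] * _HUE_H[i + 1]) - 100.0 * _HUE_H[
            i
        ] * _HUE_E[i + 1]
        den = dH * (_HUE_E[i + 1] - _HUE_E[i]) - 100.0 * _HUE_E[i + 1]
        return (num / den) % 360.0

    # ---------------------------------------------------------------- inverse
    def inverse(self, J: np.ndarray, H: np.ndarray, s: np.ndarray) -> np.ndarray:
        """(J, H, s) -> XYZ (0-100).

        The opponent pair (a, b) is recovered in closed form: with
        u = A/N_bb + 0.305 the achromatic sum R'a + G'a + 1.05 B'a equals
        u - (671 a + 6588 b)/1403, and the definition of t then gives the
        chromatic radius directly along the known hue direction.
        """
        J = np.asarray(J, dtype=float)
        s = np.asarray(s, dtype=float)
        h = self._hue_from_quadrature(H)

        Q = (4.0 / self.c) * np.sqrt(J / 100.0) * (self.A_w + 4.0) * self.F_L**0.25
        M = Q * (s / 100.0) ** 2
        C = M / self.F_L**0.25
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(
                J > 0,
                (C / (np.sqrt(J / 100.0) * (1.64 - 0.29**self.n) ** 0.73)) ** (1.0 / 0.9),
                0.0,
            )
        A = self.A_w * (J / 100.0) ** (1.0 / (self.c * self.z))
        u = A / self.N_bb + 0.305

        e_t = 0.25 * (np.cos(np.radians(h) + 2.0) + 3.8)
        k_e = (50000.0 / 13.0) * self.N_c * self.N_cb * e_t
        cos_h, sin_h = np.cos(np.radians(h)), np.sin(np.radians(h))
        denom = k_e + t * (671.0 * cos_h + 6588.0 * sin_h) / 1403.0
        r = np.where(t > 0, t * u / denom, 0.0)
        a, b = r * cos_h, r * sin_h

        ra = (460.0 * u + 451.0 * a + 288.0 * b) / 1403.0
        ga = (460.0 * u - 891.0 * a - 261.0 * b) / 1403.0
        ba = (460.0 * u - 220.0 * a - 6300.0 * b) / 1403.0
        rgb_a = np.stack([ra, ga, ba], axis=-1)
        rgb_p = _decompress(rgb_a, self.F_L)
        rgb_c = rgb_p @ np.linalg.inv(_M_HPE @ np.linalg.inv(_M_CAT02)).T
        rgb = rgb_c / self.d_scale
        return rgb @ np.linalg.inv(_M_CAT02).T

    # ------------------------------------------------------------ sRGB layer
    def srgb_forward(self, rgb: np.ndarray) -> Appearance:
        return self.forward(srgb_to_xyz(rgb))

    def srgb_inverse(
        self, J: np.ndarray, H: np.ndarray, s: np.ndarray, return_clip_fraction: bool = False
    ):
        """Inverse to sRGB, clipped to [0, 1]; optionally report clip fraction."""
        rgb = xyz_to_srgb(self.inverse(J, H, s))
        if not np.all(np.isfinite(rgb)):
            raise ValueError("non-invertible appearance attributes")
        clipped = np.clip(rgb, 0.0, 1.0)
        if return_clip_fraction:
            frac = float(np.mean(np.any(np.abs(rgb - clipped) > 1e-9, axis=-1)))
            return clipped, frac
        return clipped
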