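"""Photometric and photoreceptor action spectra on a 1 nm grid.

This module builds the weighting functions every spectral metric in the
package integrates against:

* ``V(λ)`` — the photopic luminous efficiency function (peak = 1);
* the CIE-1931-style 2° color-matching functions ``x̄, ȳ, z̄``;
* α-opic action spectra for the S-, M- and L-cone-opic and melanopic
  responses, each normalized to unit peak so that α-opic radiances come
  out in W·m⁻²·sr⁻¹.

The curves are SYNTHETIC analytic stand-ins for the official standard
tabulations, generated at import time rather than shipped as data
files:

* the color-matching functions use the multi-lobe piecewise-Gaussian
  fits of Wyman, Sloan & Shirley (J. Computer Graphics Techniques,
  2013), with ``x̄`` and ``z̄`` rescaled so the three curves integrate
  identically over 380–780 nm (the property that places an equal-energy
  spectrum exactly at x = y = 1/3);
* the α-opic curves combine the Govardovskii et al. (2000) A1
  visual-pigment template (α- plus β-band) with a single-exponential
  ocular-media density model for a young observer; the pigment peak of
  each receptor class is tuned numerically so the filtered curve peaks
  at the conventional α-opic peak wavelength (S 448 nm, M 542 nm,
  L 568 nm, melanopic 490 nm).

The approximations track the published tabulations to a few percent —
adequate for stimulus characterization, solver targets and synthetic
cohorts, and exact for every *relative* property the package relies on
(linearity, peak normalization, self-consistent CCT recovery).  Use the
official tables where standards compliance matters.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = [
    "ActionSpectraTable",
    "WAVELENGTH_GRID_NM",
    "tables",
    "ALPHA_OPIC_PEAKS_NM",
    "MAX_LUMINOUS_EFFICACY_LM_W",
]

#: Common 1 nm wavelength grid (nm) for every tabulation and integral.
WAVELENGTH_GRID_NM = np.arange(380.0, 781.0, 1.0)

#: Maximum luminous efficacy Km (lm/W) at the V(λ) peak.
MAX_LUMINOUS_EFFICACY_LM_W = 683.0

#: Peak wavelengths (nm) the α-opic curves are tuned to.
ALPHA_OPIC_PEAKS_NM = {
    "s_cone": 448.0,
    "m_cone": 542.0,
    "l_cone": 568.0,
    "melanopic": 490.0,
}


def _lobe(wl, mu, sigma_lo, sigma_hi):
    """Piecewise Gaussian with separate left/right widths."""
    sigma = np.where(wl < mu, sigma_lo, sigma_hi)
    t = (wl - mu) / sigma
    return np.exp(-0.5 * t * t)


def _cmf_xyz(wl):
    # Wyman–Sloan–Shirley analytic fits to the 1931 2° CMFs
    x = (
        1.056 * _lobe(wl, 599.8, 37.9, 31.0)
        + 0.362 * _lobe(wl, 442.0, 16.0, 26.7)
        - 0.065 * _lobe(wl, 501.1, 20.4, 26.2)
    )
    y = 0.821 * _lobe(wl, 568.8, 46.9, 40.5) + 0.286 * _lobe(wl, 530.9, 16.3, 31.1)
    z = 1.217 * _lobe(wl, 437.0, 11.8, 36.0) + 0.681 * _lobe(wl, 459.0, 26.0, 13.8)
    return np.clip(x, 0.0, None), np.clip(y, 0.0, None), np.clip(z, 0.0, None)


def _govardovskii_a1(wl, lambda_max):
    """Govardovskii (2000) A1 pigment template: α-band plus β-band."""
    x = lambda_max / wl
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (
        np.exp(69.7 * (a - x))
        + np.exp(28.0 * (0.922 - x))
        + np.exp(-14.9 * (1.104 - x))
        + 0.674
    )
    lam_b = 189.0 + 0.315 * lambda_max
    b = -40.5 + 0.195 * lambda_max
    beta = 0.26 * np.exp(-(((wl - lam_b) / b) ** 2))
    return alpha + beta


def _ocular_media_transmittance(wl):
    """10^(−D): single-exponential lens+media density of a young eye
    (D ≈ 1.0 at 400 nm falling to ≈ 0.06 by 500 nm)."""
    density = 3.03 * np.exp(-(wl - 360.0) / 36.1)
    return 10.0 ** (-np.clip(density, 0.0, None))


def _alpha_opic_curve(wl, target_peak_nm):
    """Filtered, peak-normalized receptor sensitivity whose maximum sits
    at ``target_peak_nm`` (pigment λmax found by coarse-to-fine search)."""
    media = _ocular_media_transmittance(wl)

    def peak_of(lmax):
        s = _govardovskii_a1(wl, lmax) * media
        return wl[int(np.argmax(s))]

    lo, hi = target_peak_nm - 25.0, target_peak_nm + 25.0
    best = min(
        np.arange(lo, hi + 0.25, 0.25),
        key=lambda lm: abs(peak_of(lm) - target_peak_nm),
    )
    curve = _govardovskii_a1(wl, best) * media
    return curve / curve.max()


@dataclass(frozen=True)
class ActionSpectraTable:
    """Bundle of peak-normalized action spectra on the 1 nm grid.

    Attributes
    ----------
    wavelengths_nm : ndarray
    v_lambda : ndarray
        Photopic luminous efficiency, unit peak.
    xbar, ybar, zbar : ndarray
        Color-matching functions; ``ybar`` has unit peak and all three
        share the same integral over the grid.
    s_cone, m_cone, l_cone, melanopic : ndarray
        α-opic action spectra, unit peak.
    provenance : str
        Human-readable description of how the curves were generated.
    """

    wavelengths_nm: np.ndarray
    v_lambda: np.ndarray
    xbar: np.ndarray
    ybar: np.ndarray
    zbar: np.ndarray
    s_cone: np.ndarray
    m_cone: np.ndarray
    l_cone: np.ndarray
    melanopic: np.ndarray
    provenance: str

    @property
    def v_lambda_peak_nm(self) -> float:
        """Wavelength of the V(λ) maximum on the grid."""
        return float(self.wavelengths_nm[int(np.argmax(self.v_lambda))])

    def alpha_opic(self, receptor: str) -> np.ndarray:
        return getattr(self, receptor)


@lru_cache(maxsize=1)
def tables() -> ActionSpectraTable:
    """Build (once) and return the bundled action-spectra table."""
    wl = WAVELENGTH_GRID_NM.copy()
    x, y, z = _cmf_xyz(wl)
    # equalize integrals so an equal-energy spectrum maps to x = y = 1/3,
    # then put all three on a common scale with ybar peak = 1 (a common
    # factor leaves chromaticity untouched)
    iy = np.trapezoid(y, wl)
    x *= iy / np.trapezoid(x, wl)
    z *= iy / np.trapezoid(z, wl)
    x, y, z = x / y.max(), y / y.max(), z / y.max()
    v = y.copy()
    curves = {
        name: _alpha_opic_curve(wl, peak)
        for name, peak in ALPHA_OPIC_PEAKS_NM.items()
    }
    table = ActionSpectraTable(
        wavelengths_nm=wl,
        v_lambda=v,
        xbar=x,
        ybar=y,
        zbar=z,
        provenance=(
            "synthetic analytic tabulations: Wyman-Sloan-Shirley CMF fits "
            "(integral-equalized); Govardovskii A1 pigment template with "
            "exponential ocular-media density, peaks tuned to "
            f"{ALPHA_OPIC_PEAKS_NM}"
        ),
        **curves,
    )
    for arr in (table.v_lambda, table.xbar, table.ybar, table.zbar):
        arr.setflags(write=False)
    return table
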