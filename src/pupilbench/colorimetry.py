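"""Spectral characterization of light stimuli.

Given a spectral radiance distribution ``Le(λ)`` (W·m⁻²·sr⁻¹·nm⁻¹), the
functions here compute the quantities a pupillometry study reports for
each stimulus:

* photometric luminance ``L = Km·∫V(λ)·Le(λ)·dλ`` in cd/m²
  (``Km = 683 lm/W``);
* CIE 1931 (x, y) and CIE 1976 (u′, v′) chromaticity;
* correlated color temperature (CCT) with the Planckian-locus signed
  distance ``duv``, undefined when the chromaticity sits farther than
  |duv| > 0.05 from the locus;
* α-opic radiances ``∫s_r(λ)·Le(λ)·dλ`` for the S-, M-, L-cone-opic and
  melanopic responses, with peak-normalized action spectra so the
  result carries the units W·m⁻²·sr⁻¹.

All integrals are trapezoidal on a common 1 nm grid; radiance outside
the tabulated 380–780 nm range is treated as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from pupilbench.action_spectra import (
    MAX_LUMINOUS_EFFICACY_LM_W,
    WAVELENGTH_GRID_NM,
    tables,
)

__all__ = [
    "Spectrum",
    "AlphaOpicValues",
    "StimulusMetrics",
    "luminance",
    "chromaticity",
    "cct",
    "alpha_opic",
    "stimulus_metrics",
    "planckian_spectrum",
    "UndefinedChromaticityError",
    "DUV_LIMIT",
]

#: |duv| beyond which a CCT is not meaningful.
DUV_LIMIT = 0.05

_C2_NM_K = 1.4388e7  # second radiation constant, nm·K


class UndefinedChromaticityError(ValueError):
    """Spectrum has no photometric content; chromaticity is undefined."""


@dataclass(frozen=True)
class Spectrum:
    """Spectral radiance on a strictly increasing wavelength grid.

    Stored resampled to the common 1 nm grid 380–780 nm; construct from
    arbitrary (sorted, step ≤ 5 nm) input grids via :meth:`from_samples`.
    Radiance is W·m⁻²·sr⁻¹·nm⁻¹ and must be non-negative.
    """

    wavelengths_nm: np.ndarray
    radiance: np.ndarray

    def __post_init__(self):
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        ra = np.asarray(self.radiance, dtype=float)
        if wl.ndim != 1 or wl.shape != ra.shape:
            raise ValueError("wavelengths and radiance must be 1-D and same length")
        if wl.size < 2:
            raise ValueError("a spectrum needs at least two samples to integrate")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(~np.isfinite(ra)) or np.any(ra < 0):
            raise ValueError("radiance must be finite and non-negative")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "radiance", ra)

    @classmethod
    def from_samples(cls, wavelengths_nm, radiance) -> "Spectrum":
        """Validate and linearly resample onto the 1 nm grid 380–780 nm.

        The input must cover [380, 780] nm with a grid step of at most
        5 nm; values outside the grid are dropped (treated as zero by
        every metric anyway).
        """
        wl = np.asarray(wavelengths_nm, dtype=float)
        ra = np.asarray(radiance, dtype=float)
        probe = cls(wl, ra)  # runs validity checks
        if wl[0] > WAVELENGTH_GRID_NM[0] or wl[-1] < WAVELENGTH_GRID_NM[-1]:
            raise ValueError(
                f"spectrum must cover [{WAVELENGTH_GRID_NM[0]:.0f}, "
                f"{WAVELENGTH_GRID_NM[-1]:.0f}] nm, got "
                f"[{wl[0]:.1f}, {wl[-1]:.1f}]"
            )
        if np.max(np.diff(wl)) > 5.0 + 1e-9:
            raise ValueError("input grid step must be ≤ 5 nm")
        grid = WAVELENGTH_GRID_NM
        return cls(grid.copy(), np.interp(grid, probe.wavelengths_nm, probe.radiance))

    @classmethod
    def monochromatic(cls, wavelength_nm: float, radiance: float = 1.0) -> "Spectrum":
        """A single 1 nm-wide line carrying total radiance ``radiance``
        W·m⁻²·sr⁻¹ (one nonzero sample on the 1 nm grid)."""
        grid = WAVELENGTH_GRID_NM.copy()
        ra = np.zeros_like(grid)
        idx = int(np.argmin(np.abs(grid - wavelength_nm)))
        ra[idx] = radiance
        return cls(grid, ra)

    def on_common_grid(self) -> "Spectrum":
        if (
            self.wavelengths_nm.shape == WAVELENGTH_GRID_NM.shape
            and np.array_equal(self.wavelengths_nm, WAVELENGTH_GRID_NM)
        ):
            return self
        return Spectrum.from_samples(self.wavelengths_nm, self.radiance)

    def scaled(self, k: float) -> "Spectrum":
        return Spectrum(self.wavelengths_nm, self.radiance * k)


@dataclass(frozen=True)
class AlphaOpicValues:
    """α-opic radiances in W·m⁻²·sr⁻¹ (Table-style stimulus columns)."""

    s_cone: float
    m_cone: float
    l_cone: float
    melanopic: float

    def as_dict(self) -> dict:
        return {
            "s_cone": self.s_cone,
            "m_cone": self.m_cone,
            "l_cone": self.l_cone,
            "melanopic": self.melanopic,
        }


@dataclass(frozen=True)
class StimulusMetrics:
    """Full photometric/colorimetric description of one stimulus."""

    luminance_cdm2: float
    x: float
    y: float
    u_prime: float
    v_prime: float
    cct_K: Optional[float]
    duv: Optional[float]
    alpha_opic: AlphaOpicValues

    def as_dict(self) -> dict:
        return {
            "luminance_cdm2": self.luminance_cdm2,
            "x": self.x,
            "y": self.y,
            "u_prime": self.u_prime,
            "v_prime": self.v_prime,
            "cct_K": self.cct_K,
            "duv": self.duv,
            "alpha_opic": self.alpha_opic.as_dict(),
        }


def _integrate(weight: np.ndarray, spec: Spectrum) -> float:
    s = spec.on_common_grid()
    return float(np.trapezoid(weight * s.radiance, s.wavelengths_nm))


def luminance(spec: Spectrum) -> float:
    """Photometric luminance in cd/m²: ``683·∫V(λ)Le(λ)dλ``."""
    return MAX_LUMINOUS_EFFICACY_LM_W * _integrate(tables().v_lambda, spec)


def chromaticity(spec: Spectrum) -> tuple[float, float, float, float]:
    """CIE 1931 (x, y) and CIE 1976 (u′, v′) chromaticity coordinates."""
    t = tables()
    X = _integrate(t.xbar, spec)
    Y = _integrate(t.ybar, spec)
    Z = _integrate(t.zbar, spec)
    total = X + Y + Z
    if total <= 0.0:
        raise UndefinedChromaticityError("zero spectrum has no chromaticity")
    x, y = X / total, Y / total
    return (x, y, *_xy_to_uv_prime(x, y))


def _xy_to_uv_prime(x: float, y: float) -> tuple[float, float]:
    den = -2.0 * x + 12.0 * y + 3.0
    return 4.0 * x / den, 9.0 * y / den


def alpha_opic(spec: Spectrum) -> AlphaOpicValues:
    """α-opic radiances against the peak-normalized action spectra."""
    t = tables()
    return AlphaOpicValues(
        s_cone=_integrate(t.s_cone, spec),
        m_cone=_integrate(t.m_cone, spec),
        l_cone=_integrate(t.l_cone, spec),
        melanopic=_integrate(t.melanopic, spec),
    )


# ---------------------------------------------------------------------------
# Planckian locus and CCT


def planckian_spectrum(temperature_K: float, luminance_cdm2: Optional[float] = None) -> Spectrum:
    """Blackbody spectral radiance shape at ``temperature_K`` on the 1 nm
    grid, optionally scaled to a target luminance."""
    if temperature_K <= 0:
        raise ValueError("temperature must be positive")
    wl = WAVELENGTH_GRID_NM
    ra = wl**-5.0 / (np.exp(_C2_NM_K / (wl * temperature_K)) - 1.0)
    ra = ra / ra.max()
    spec = Spectrum(wl.copy(), ra)
    if luminance_cdm2 is not None:
        spec = spec.scaled(luminance_cdm2 / luminance(spec))
    return spec


def _uv_1960(x: float, y: float) -> tuple[float, float]:
    # CIE 1960 (u, v): u = u', v = (2/3)·v'
    up, vp = _xy_to_uv_prime(x, y)
    return up, vp * 2.0 / 3.0


def _planckian_locus_uv(n_per_decade_step: float = 0.01):
    temps = [1000.0]
    while temps[-1] < 25000.0:
        temps.append(temps[-1] * (1.0 + n_per_decade_step))
    temps = np.array(temps)
    uv = np.empty((temps.size, 2))
    for i, T in enumerate(temps):
        spec = planckian_spectrum(T)
        x, y, _, _ = chromaticity(spec)
        uv[i] = _uv_1960(x, y)
    return temps, uv


_LOCUS_CACHE: Optional[tuple[np.ndarray, np.ndarray]] = None


def _locus() -> tuple[np.ndarray, np.ndarray]:
    global _LOCUS_CACHE
    if _LOCUS_CACHE is None:
        _LOCUS_CACHE = _planckian_locus_uv()
    return _LOCUS_CACHE


def cct(
    spec: Optional[Spectrum] = None,
    *,
    u_prime: Optional[float] = None,
    v_prime: Optional[float] = None,
) -> tuple[Optional[float], float]:
    """Correlated color temperature and signed Planckian distance.

    Nearest point on a 1%-step Planckian-locus table (1000–25000 K) with
    parabolic refinement of the squared distance over the temperature
    index.  ``duv`` is the distance in CIE 1960 (u, v) space, signed
    positive above the locus (v greater than the locus).  When
    |duv| > 0.05 the CCT is reported as ``None`` (off-locus stimulus).

    Accepts either a :class:`Spectrum` or explicit (u′, v′) coordinates.
    """
    if spec is not None:
        _, _, u_prime, v_prime = chromaticity(spec)
    if u_prime is None or v_prime is None:
        raise ValueError("provide a spectrum or both u_prime and v_prime")
    u, v = u_prime, v_prime * 2.0 / 3.0
    temps, uv = _locus()
    d2 = (uv[:, 0] - u) ** 2 + (uv[:, 1] - v) ** 2
    i = int(np.argmin(d2))
    if 0 < i < temps.size - 1:
        # parabolic refinement of distance² over log-temperature
        y0, y1, y2 = d2[i - 1], d2[i], d2[i + 2 - 1]
        denom = y0 - 2.0 * y1 + y2
        frac = 0.0 if denom == 0.0 else 0.5 * (y0 - y2) / denom
        frac = float(np.clip(frac, -0.5, 0.5))
        log_t = (
            math.log(temps[i])
            + frac * (math.log(temps[i + 1]) - math.log(temps[i - 1])) / 2.0
        )
        t_best = math.exp(log_t)
        d_min2 = max(y1 - 0.25 * (y0 - y2) * frac, 0.0)
    else:
        t_best = float(temps[i])
        d_min2 = d2[i]
    duv = math.sqrt(d_min2)
    # sign: above the locus (towards green, larger v) is positive
    spec_t = planckian_spectrum(t_best)
    x_t, y_t, _, _ = chromaticity(spec_t)
    _, v_locus = _uv_1960(x_t, y_t)
    if v < v_locus:
        duv = -duv
    if abs(duv) > DUV_LIMIT:
        return None, duv
    return t_best, duv


def stimulus_metrics(spec: Spectrum) -> StimulusMetrics:
    """All reported metrics of a stimulus spectrum in one pass."""
    lum = luminance(spec)
    x, y, up, vp = chromaticity(spec)
    cct_K, duv = cct(u_prime=up, v_prime=vp)
    return StimulusMetrics(
        luminance_cdm2=lum,
        x=x,
        y=y,
        u_prime=up,
        v_prime=vp,
        cct_K=cct_K,
        duv=duv,
        alpha_opic=alpha_opic(spec),
    )
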