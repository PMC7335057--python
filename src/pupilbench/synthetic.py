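"""Synthetic stimuli and pupil-trace cohorts with ground truth.

Real benchmarking data — multi-primary LED stimulus spectra and 120 Hz
video-pupillometry recordings — are expensive to collect and rarely
shareable.  This module fabricates both, returning the exact ground
truth alongside every artifact so the preprocessing and benchmarking
stages can be validated end to end:

* a 15-channel LED luminaire model (eleven narrowband Gaussians plus
  four phosphor-converted whites approximated as two-Gaussian SPDs
  tuned to their nominal CCT), with a deterministic non-negative
  least-squares solver that mixes channels to a chromaticity +
  luminance target;
* pupil traces with a phasic (cone-driven) constriction that decays
  after light onset, a sustained (melanopsin-weighted) constriction
  that builds towards a steady state, Gaussian measurement noise,
  Poisson-scheduled blink dropouts with low quality scores, and
  occasional single-sample spikes;
* cohorts of subjects whose parameters scatter around population means
  (interpersonal SD ≈ 0.75 mm on the baseline diameter, intrapersonal
  SD ≈ 0.3 mm per presentation), with re-adaptation anchor
  presentations interleaved between stimuli.

The trace generator is a didactic stand-in, not a mechanistic model of
the ipRGC pathway: its contract is sample-exact ground truth and
qualitative realism (sustained constriction scaling with melanopic
content), not physiological fidelity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq, nnls

from pupilbench.colorimetry import (
    Spectrum,
    StimulusMetrics,
    cct as compute_cct,
    chromaticity,
    luminance,
    planckian_spectrum,
    stimulus_metrics,
)
from pupilbench.action_spectra import WAVELENGTH_GRID_NM
from pupilbench.preprocessing import PupilTrace

__all__ = [
    "LedChannel",
    "default_channels",
    "mix_spectrum",
    "solve_weights",
    "SubjectParams",
    "GroundTruth",
    "generate_trace",
    "generate_cohort",
    "CohortMember",
    "GamutError",
]

# printed channel list of the reference 15-channel luminaire
_NARROWBAND_PEAKS_NM = (420, 450, 470, 505, 530, 545, 590, 610, 630, 660, 720)
_NARROWBAND_FWHM_NM = (14, 18, 25, 29, 33, 105, 78, 17, 16, 17, 29)
_WHITE_CCTS_K = (2700, 4000, 5000, 5500)


class GamutError(ValueError):
    """Chromaticity/luminance target is unreachable with these channels."""


@dataclass(frozen=True)
class LedChannel:
    """One LED primary: a narrowband Gaussian or a phosphor-white
    two-Gaussian approximation labeled by its nominal CCT."""

    peak_nm: float
    fwhm_nm: float
    kind: str = "narrowband"  # or "phosphor_white"
    cct_label_K: Optional[float] = None
    phosphor_peak_nm: Optional[float] = None
    phosphor_fwhm_nm: Optional[float] = None
    phosphor_ratio: Optional[float] = None  # phosphor amplitude per pump amplitude

    def __post_init__(self):
        if not (380.0 <= self.peak_nm <= 780.0):
            raise ValueError("peak wavelength must lie in [380, 780] nm")
        if self.fwhm_nm <= 0:
            raise ValueError("FWHM must be positive")

    def basis_spectrum(self) -> Spectrum:
        """Unit-amplitude SPD of this channel on the 1 nm grid."""
        wl = WAVELENGTH_GRID_NM
        ra = _gaussian(wl, self.peak_nm, self.fwhm_nm)
        if self.kind == "phosphor_white":
            ra = ra + self.phosphor_ratio * _gaussian(
                wl, self.phosphor_peak_nm, self.phosphor_fwhm_nm
            )
        return Spectrum(wl.copy(), ra)


def _gaussian(wl, peak, fwhm):
    return np.exp(-4.0 * math.log(2.0) * ((wl - peak) / fwhm) ** 2)


def _tune_white(cct_label: float) -> LedChannel:
    """Phosphor-white channel: 450 nm pump + broad phosphor band, the
    pump/phosphor ratio solved so the mixed SPD hits the labeled CCT."""
    pump_nm, pump_fwhm = 450.0, 20.0
    # warmer whites use red-shifted phosphors; interpolate the band peak
    phos_nm = float(np.interp(cct_label, [2700.0, 4000.0, 5000.0, 5500.0],
                              [605.0, 585.0, 572.0, 568.0]))
    phos_fwhm = 110.0
    wl = WAVELENGTH_GRID_NM

    def cct_of(ratio):
        ra = _gaussian(wl, pump_nm, pump_fwhm) + ratio * _gaussian(wl, phos_nm, phos_fwhm)
        t, duv = compute_cct(Spectrum(wl.copy(), ra))
        if t is not None:
            return t
        # off-locus: pump-heavy mixes sit below the locus (blue, duv < 0),
        # phosphor-heavy above (yellow-green, duv > 0); keep cct_of monotone
        return 500.0 if duv > 0 else 1e5

    target = float(cct_label)
    ratio = brentq(lambda r: cct_of(r) - target, 0.05, 50.0, xtol=1e-4)
    return LedChannel(
        peak_nm=pump_nm,
        fwhm_nm=pump_fwhm,
        kind="phosphor_white",
        cct_label_K=target,
        phosphor_peak_nm=phos_nm,
        phosphor_fwhm_nm=phos_fwhm,
        phosphor_ratio=float(ratio),
    )


_CHANNEL_CACHE: Optional[tuple] = None


def default_channels() -> tuple:
    """The 15 channels of the reference luminaire: 11 narrowband LEDs
    (printed peaks/FWHMs) + 4 phosphor-converted whites."""
    global _CHANNEL_CACHE
    if _CHANNEL_CACHE is None:
        narrow = tuple(
            LedChannel(peak_nm=float(p), fwhm_nm=float(f))
            for p, f in zip(_NARROWBAND_PEAKS_NM, _NARROWBAND_FWHM_NM)
        )
        whites = tuple(_tune_white(t) for t in _WHITE_CCTS_K)
        _CHANNEL_CACHE = narrow + whites
    return _CHANNEL_CACHE


def mix_spectrum(channels: Sequence[LedChannel], weights: Sequence[float]) -> Spectrum:
    """Weighted sum of channel basis spectra (weights ≥ 0)."""
    w = np.asarray(list(weights), dtype=float)
    if w.size != len(channels):
        raise ValueError("one weight per channel required")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    wl = WAVELENGTH_GRID_NM
    total = np.zeros_like(wl)
    for ch, wi in zip(channels, w):
        if wi != 0.0:
            total = total + wi * ch.basis_spectrum().radiance
    return Spectrum(wl.copy(), total)


def solve_weights(
    channels: Sequence[LedChannel],
    *,
    luminance_cdm2: float,
    u_prime: Optional[float] = None,
    v_prime: Optional[float] = None,
    cct_K: Optional[float] = None,
    uv_tol: float = 1e-3,
    lum_rel_tol: float = 5e-3,
) -> np.ndarray:
    """Solve channel weights hitting a chromaticity + luminance target.

    The target is given either as CIE 1976 (u′, v′) or as a CCT on the
    Planckian locus.  Because tristimulus values are linear in the
    weights, the target fixes the (X, Y, Z) vector exactly (Y from the
    luminance, X and Z from the chromaticity), and a non-negative
    least-squares fit over the channel tristimulus matrix gives a
    deterministic solution.  Raises :class:`GamutError` when the
    residual leaves the achieved metrics outside tolerance.
    """
    if cct_K is not None:
        x_t, y_t, u_prime, v_prime = chromaticity(planckian_spectrum(cct_K))
    if u_prime is None or v_prime is None:
        raise ValueError("provide u_prime/v_prime or cct_K")
    den = 6.0 * u_prime - 16.0 * v_prime + 12.0
    x_t = 9.0 * u_prime / den
    y_t = 4.0 * v_prime / den
    if y_t <= 0:
        raise GamutError("target chromaticity has non-positive y")

    from pupilbench.action_spectra import tables

    t = tables()
    basis = np.stack([ch.basis_spectrum().radiance for ch in channels], axis=1)
    wl = WAVELENGTH_GRID_NM
    a = np.stack(
        [
            np.trapezoid(t.xbar[:, None] * basis, wl, axis=0),
            np.trapezoid(t.ybar[:, None] * basis, wl, axis=0),
            np.trapezoid(t.zbar[:, None] * basis, wl, axis=0),
        ]
    )
    y_target = luminance_cdm2 / 683.0
    s_total = y_target / y_t
    target = np.array([x_t * s_total, y_target, (1.0 - x_t - y_t) * s_total])
    # scale rows for a balanced residual, then solve NNLS
    scale = 1.0 / np.abs(target).max()
    w, _ = nnls(a * scale, target * scale)

    achieved = mix_spectrum(channels, w)
    lum = luminance(achieved)
    if lum <= 0:
        raise GamutError("target outside channel gamut (zero solution)")
    _, _, up, vp = chromaticity(achieved)
    if (
        abs(up - u_prime) > uv_tol
        or abs(vp - v_prime) > uv_tol
        or abs(lum - luminance_cdm2) / luminance_cdm2 > lum_rel_tol
    ):
        raise GamutError(
            f"target (u'={u_prime:.4f}, v'={v_prime:.4f}, L={luminance_cdm2:.1f}) "
            f"outside gamut: achieved (u'={up:.4f}, v'={vp:.4f}, L={lum:.1f})"
        )
    return w


# ---------------------------------------------------------------------------
# pupil-trace generation


@dataclass(frozen=True)
class SubjectParams:
    """Per-subject generator parameters.

    ``sustained_gain_mm_per_unit`` multiplies the stimulus melanopic
    radiance (W·m⁻²·sr⁻¹) to set the sustained constriction depth; the
    designed steady-state diameter under a stimulus with melanopic
    radiance ``M`` is ``baseline − gain·M``.
    """

    baseline_diameter_mm: float = 6.5
    phasic_amplitude_mm: float = 1.2
    phasic_tau_s: float = 1.5
    sustained_gain_mm_per_unit: float = 1.0
    redilation_tau_s: float = 30.0
    noise_sd_mm: float = 0.08
    blink_rate_hz: float = 0.2
    blink_duration_ms: float = 150.0
    spike_rate_hz: float = 0.02
    spike_amplitude_mm: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not (4.0 <= self.baseline_diameter_mm <= 9.0):
            raise ValueError("baseline diameter must lie in [4, 9] mm")
        for name in ("phasic_amplitude_mm", "phasic_tau_s", "redilation_tau_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("sustained_gain_mm_per_unit", "noise_sd_mm", "blink_rate_hz",
                     "blink_duration_ms", "spike_rate_hz", "spike_amplitude_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def steady_state_mm(self, melanopic_radiance: float) -> float:
        """Closed-form t→∞ diameter under a given melanopic radiance."""
        return float(
            np.clip(
                self.baseline_diameter_mm
                - self.sustained_gain_mm_per_unit * melanopic_radiance,
                1.5,
                9.0,
            )
        )


@dataclass(frozen=True)
class GroundTruth:
    """Noise- and artifact-free truth aligned sample-for-sample with the
    emitted raw trace."""

    clean_diameter_mm: np.ndarray
    blink_mask: np.ndarray
    spike_indices: np.ndarray
    steady_state_mm: float


def generate_trace(
    stimulus: StimulusMetrics,
    subject: SubjectParams,
    duration_s: float = 300.0,
    fs: float = 120.0,
) -> tuple[PupilTrace, GroundTruth]:
    """Simulate one raw pupil recording under a constant stimulus.

    The noise-free diameter is

    ``d(t) = baseline − A·exp(−t/τ_phasic) − g·M·(1 − exp(−t/τ_redil))``

    clipped to [1.5, 9] mm, where ``M`` is the stimulus melanopic
    radiance: a cone-driven transient constriction recovering with
    ``τ_phasic`` and a melanopsin-weighted sustained constriction
    approaching its steady state with ``τ_redil``.  On top of it the raw
    trace carries Gaussian noise, Poisson-scheduled blink dropouts
    (missing diameter, blink flag set, low quality score) and sparse
    single-sample spikes with normal quality (visible only to the
    velocity filter).  Fully determined by ``subject.seed``.
    """
    if duration_s < 5.0:
        raise ValueError("duration must be at least 5 s")
    rng = np.random.default_rng(subject.seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    mel = stimulus.alpha_opic.melanopic
    clean = (
        subject.baseline_diameter_mm
        - subject.phasic_amplitude_mm * np.exp(-t / subject.phasic_tau_s)
        - subject.sustained_gain_mm_per_unit * mel
        * (1.0 - np.exp(-t / subject.redilation_tau_s))
    )
    clean = np.clip(clean, 1.5, 9.0)

    raw = clean + rng.normal(0.0, subject.noise_sd_mm, size=n)
    quality = np.clip(100.0 - rng.exponential(0.5, size=n), 0.0, 100.0)

    blink_mask = np.zeros(n, dtype=bool)
    n_blinks = rng.poisson(subject.blink_rate_hz * duration_s)
    blink_len = max(int(round(subject.blink_duration_ms / 1000.0 * fs)), 1)
    for start in np.sort(rng.integers(0, n, size=n_blinks)):
        blink_mask[start : start + blink_len] = True
    raw[blink_mask] = np.nan
    quality[blink_mask] = rng.uniform(0.0, 50.0, size=int(blink_mask.sum()))

    n_spikes = rng.poisson(subject.spike_rate_hz * duration_s)
    candidates = np.flatnonzero(~blink_mask)
    spike_idx = (
        rng.choice(candidates, size=min(n_spikes, candidates.size), replace=False)
        if candidates.size
        else np.empty(0, dtype=int)
    )
    raw[spike_idx] += rng.choice([-1.0, 1.0], size=spike_idx.size) * subject.spike_amplitude_mm

    raw = np.where(np.isnan(raw), raw, np.clip(raw, 0.6, 9.9))
    trace = PupilTrace(
        time_s=t,
        diameter_mm=raw,
        quality_pct=quality,
        blink=blink_mask,
        meta={"fs": fs, "seed": subject.seed},
    )
    truth = GroundTruth(
        clean_diameter_mm=clean,
        blink_mask=blink_mask,
        spike_indices=np.sort(spike_idx),
        steady_state_mm=subject.steady_state_mm(mel),
    )
    return trace, truth


@dataclass(frozen=True)
class CohortMember:
    subject_id: str
    params: SubjectParams
    traces: dict  # stimulus label -> PupilTrace
    anchors: dict  # stimulus label -> anchor PupilTrace preceding it
    truths: dict  # stimulus label -> GroundTruth


def generate_cohort(
    stimuli: dict,
    n_subjects: int = 20,
    *,
    anchor: Optional[StimulusMetrics] = None,
    inter_sd_mm: float = 0.75,
    intra_sd_mm: float = 0.3,
    gain_rel_sd: float = 0.3,
    duration_s: float = 300.0,
    anchor_duration_s: float = 300.0,
    fs: float = 120.0,
    seed: int = 0,
    population: SubjectParams = SubjectParams(),
    steady_targets_mm: Optional[dict] = None,
) -> list[CohortMember]:
    """Simulate a full randomized-presentation cohort.

    Parameters
    ----------
    stimuli : dict label -> StimulusMetrics
        Test stimuli, each presented once per subject for
        ``duration_s``, preceded by an anchor presentation.
    anchor : StimulusMetrics, optional
        Re-adaptation stimulus; defaults to the first stimulus.  The
        generator resets the pupil to baseline at each stimulus onset
        (the anchor→stimulus re-adaptation transient is not modeled).
    inter_sd_mm / intra_sd_mm : float
        Interpersonal SD of the baseline diameter across subjects, and
        intrapersonal SD added per presentation.
    gain_rel_sd : float
        Relative interpersonal SD of the sustained (melanopsin) gain —
        some observers show a stronger spectral pupil dynamic than
        others.  Ignored when ``steady_targets_mm`` pins the gain.
    steady_targets_mm : dict label -> float, optional
        When given, each subject's ``sustained_gain`` is re-derived per
        stimulus so the designed steady-state diameter equals the
        target exactly (parameter-recovery cohorts).

    Returns a list of :class:`CohortMember`; ground truth for every
    presentation rides along.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    rng = np.random.default_rng(seed)
    labels = list(stimuli)
    members = []
    for s in range(n_subjects):
        baseline = float(
            np.clip(rng.normal(population.baseline_diameter_mm, inter_sd_mm), 4.0, 9.0)
        )
        gain = float(
            max(
                rng.normal(
                    population.sustained_gain_mm_per_unit,
                    gain_rel_sd * population.sustained_gain_mm_per_unit,
                ),
                0.0,
            )
        )
        base_params = replace(
            population,
            baseline_diameter_mm=baseline,
            sustained_gain_mm_per_unit=gain,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        order = list(rng.permutation(labels))
        traces, anchors_d, truths = {}, {}, {}
        for label in order:
            stim = stimuli[label]
            jitter = rng.normal(0.0, intra_sd_mm)
            b = float(np.clip(baseline + jitter, 4.0, 9.0))
            params = replace(
                base_params,
                baseline_diameter_mm=b,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            if steady_targets_mm is not None and label in steady_targets_mm:
                mel = stim.alpha_opic.melanopic
                gain = (b - steady_targets_mm[label]) / mel if mel > 0 else 0.0
                if gain < 0:
                    raise ValueError(
                        f"steady target {steady_targets_mm[label]} mm above the "
                        f"baseline {b:.2f} mm; increase the population baseline"
                    )
                params = replace(params, sustained_gain_mm_per_unit=gain)
            anchor_stim = anchor if anchor is not None else stimuli[labels[0]]
            anchor_params = replace(params, seed=int(rng.integers(0, 2**31 - 1)))
            anchors_d[label], _ = generate_trace(
                anchor_stim, anchor_params, anchor_duration_s, fs
            )
            traces[label], truths[label] = generate_trace(stim, params, duration_s, fs)
        members.append(
            CohortMember(
                subject_id=f"S{s + 1:02d}",
                params=base_params,
                traces=traces,
                anchors=anchors_d,
                truths=truths,
            )
        )
    return members
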