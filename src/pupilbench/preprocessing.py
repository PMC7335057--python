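"""Pupil-trace artifact removal and smoothing.

Raw video-pupillometry traces carry blink dropouts, low-confidence
ellipse fits and single-sample spikes from gaze jumps.  The cleaning
pipeline applies, in order:

1. blink removal (flagged samples → missing);
2. quality filtering (ellipse-fit confidence below 97% → missing);
3. velocity-percentile outlier rejection — the first-difference
   velocity profile of the recording is computed and samples whose
   incoming velocity falls strictly outside the [0.007, 99.993]
   percentile band are dropped;
4. linear interpolation of all gaps (edge gaps filled with the nearest
   present value, since linear extrapolation can turn unphysical);
5. Savitzky–Golay smoothing (window 3001 samples ≈ 25 s at 120 Hz,
   polynomial order 3), with the first 3 s of the trace left
   untouched so the phasic constriction onset is not flattened.

Every stage preserves the time axis and sample count; stages only mark
diameters missing (NaN) or replace values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "PupilTrace",
    "PreprocessParams",
    "CleanResult",
    "quality_filter",
    "blink_filter",
    "velocity_filter",
    "interpolate_gaps",
    "smooth",
    "clean_trace",
    "EmptyTraceError",
]

_TIME_TOL_S = 1e-6  # allowed jitter of the uniform sampling step


class EmptyTraceError(ValueError):
    """No usable samples remain in (or were supplied with) the trace."""


@dataclass(frozen=True)
class PupilTrace:
    """Uniformly sampled pupil-diameter time series.

    Attributes
    ----------
    time_s : ndarray
        Strictly increasing, uniform to within 1 µs.
    diameter_mm : ndarray
        Diameter in mm; NaN marks missing samples.  Present values must
        lie in (0.5, 10) mm.
    quality_pct : ndarray
        Per-sample ellipse-fit confidence in [0, 100].
    blink : ndarray of bool
        Detector blink flags.
    meta : dict
        Free-form metadata (subject id, stimulus label, eye, ...).
    """

    time_s: np.ndarray
    diameter_mm: np.ndarray
    quality_pct: np.ndarray
    blink: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.time_s, dtype=float)
        d = np.asarray(self.diameter_mm, dtype=float)
        q = np.asarray(self.quality_pct, dtype=float)
        b = np.asarray(self.blink, dtype=bool)
        n = t.size
        if not (d.size == q.size == b.size == n) or n < 2:
            raise ValueError("trace arrays must share a length of at least 2")
        steps = np.diff(t)
        if np.any(steps <= 0):
            raise ValueError("time axis must be strictly increasing")
        if np.ptp(steps) > _TIME_TOL_S:
            raise ValueError("time axis must be uniform to within 1 µs")
        present = ~np.isnan(d)
        if np.any((d[present] <= 0.5) | (d[present] >= 10.0)):
            raise ValueError("present diameters must lie in (0.5, 10) mm")
        if np.any((q < 0) | (q > 100)):
            raise ValueError("quality must lie in [0, 100] %")
        for name, arr in (("time_s", t), ("diameter_mm", d),
                          ("quality_pct", q), ("blink", b)):
            object.__setattr__(self, name, arr)

    @property
    def fs(self) -> float:
        """Sampling rate in Hz."""
        return 1.0 / float(np.mean(np.diff(self.time_s)))

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.diameter_mm).sum())

    @property
    def n_present(self) -> int:
        return self.time_s.size - self.n_missing

    def with_diameter(self, diameter_mm: np.ndarray) -> "PupilTrace":
        return replace(self, diameter_mm=np.asarray(diameter_mm, dtype=float))


@dataclass(frozen=True)
class PreprocessParams:
    """Cleaning-pipeline parameters (defaults follow the published
    Smart-Eye processing recipe this package benchmarks against).

    ``sg_window_samples`` is forced odd; 3001 is the nearest odd window
    to a 3000-sample (25 s at 120 Hz) span.
    """

    min_quality_pct: float = 97.0
    vel_hi_pctl: float = 99.993
    vel_lo_pctl: float = 0.007
    sg_window_samples: int = 3001
    sg_polyorder: int = 3
    unsmoothed_lead_s: float = 3.0

    def __post_init__(self):
        if not (0.0 < self.vel_lo_pctl < self.vel_hi_pctl < 100.0):
            raise ValueError("need 0 < lo percentile < hi percentile < 100")
        if self.sg_window_samples % 2 == 0:
            object.__setattr__(self, "sg_window_samples", self.sg_window_samples + 1)
        if self.sg_window_samples < self.sg_polyorder + 2:
            raise ValueError("SG window must be ≥ polyorder + 2")
        if not (0.0 <= self.min_quality_pct <= 100.0):
            raise ValueError("quality threshold must lie in [0, 100]")


@dataclass(frozen=True)
class CleanResult:
    """A cleaned trace plus per-stage removal bookkeeping."""

    trace: PupilTrace
    removed: dict  # stage name -> number of samples newly marked missing


def _mark_missing(trace: PupilTrace, mask: np.ndarray) -> PupilTrace:
    d = trace.diameter_mm.copy()
    d[mask] = np.nan
    return trace.with_diameter(d)


def blink_filter(trace: PupilTrace) -> PupilTrace:
    """Mark blink-flagged samples missing (no temporal padding)."""
    return _mark_missing(trace, trace.blink)


def quality_filter(trace: PupilTrace, params: PreprocessParams = PreprocessParams()) -> PupilTrace:
    """Mark samples with fit confidence below the threshold missing."""
    low = trace.quality_pct < params.min_quality_pct
    out = _mark_missing(trace, low)
    if out.n_present == 0:
        raise EmptyTraceError("quality filter removed every sample")
    return out


def velocity_filter(trace: PupilTrace, params: PreprocessParams = PreprocessParams()) -> PupilTrace:
    """Drop samples whose incoming diameter velocity is an extreme
    outlier of the recording's velocity distribution.

    Velocities are first differences between consecutive *present*
    samples divided by their time separation.  The later sample of a
    pair whose velocity lies strictly outside the
    [``vel_lo_pctl``, ``vel_hi_pctl``] percentile band is marked
    missing.  With fewer than 1000 present samples the percentiles are
    not meaningful; the trace passes through with a warning.
    """
    present_idx = np.flatnonzero(~np.isnan(trace.diameter_mm))
    if present_idx.size < 1000:
        warnings.warn(
            f"velocity filter skipped: only {present_idx.size} present samples "
            "(< 1000), percentile thresholds unreliable",
            stacklevel=2,
        )
        return trace
    d = trace.diameter_mm[present_idx]
    t = trace.time_s[present_idx]
    vel = np.diff(d) / np.diff(t)
    # thresholds are attained order statistics, so a distribution with no
    # genuine outliers (e.g. a constant or already-cleaned trace) loses
    # nothing: only samples strictly beyond an attained velocity go
    lo = np.percentile(vel, params.vel_lo_pctl, method="lower")
    hi = np.percentile(vel, params.vel_hi_pctl, method="higher")
    bad_pairs = (vel < lo) | (vel > hi)
    mask = np.zeros(trace.time_s.size, dtype=bool)
    mask[present_idx[1:][bad_pairs]] = True
    return _mark_missing(trace, mask)


def interpolate_gaps(trace: PupilTrace) -> PupilTrace:
    """Fill every missing sample: interior gaps linearly between the
    bounding present samples, edge gaps with the nearest present value."""
    d = trace.diameter_mm
    present = ~np.isnan(d)
    if present.sum() < 2:
        raise EmptyTraceError("need at least two present samples to interpolate")
    filled = np.interp(trace.time_s, trace.time_s[present], d[present])
    return trace.with_diameter(filled)


def smooth(trace: PupilTrace, params: PreprocessParams = PreprocessParams()) -> PupilTrace:
    """Savitzky–Golay smoothing with an unsmoothed lead-in.

    The filter fits a local polynomial (order ``sg_polyorder``) over a
    sliding ``sg_window_samples`` window; near the edges the polynomial
    is fit on the truncated terminal window and re-evaluated.  Samples
    with ``t < unsmoothed_lead_s`` (relative to the trace start) are
    returned unmodified.  A window longer than the trace shrinks to the
    largest odd length that fits, with a warning.
    """
    d = trace.diameter_mm
    if np.any(np.isnan(d)):
        raise ValueError("smooth requires a gap-free trace; interpolate first")
    n = d.size
    window = params.sg_window_samples
    if window > n:
        window = n if n % 2 == 1 else n - 1
        warnings.warn(
            f"SG window shrunk to {window} samples (trace shorter than requested window)",
            stacklevel=2,
        )
    if window < params.sg_polyorder + 2:
        return trace  # too short to smooth at all
    sm = savgol_filter(d, window_length=window, polyorder=params.sg_polyorder,
                       mode="interp")
    lead = trace.time_s < trace.time_s[0] + params.unsmoothed_lead_s
    out = sm.copy()
    out[lead] = d[lead]
    return trace.with_diameter(out)


def clean_trace(raw: PupilTrace, params: PreprocessParams = PreprocessParams()) -> CleanResult:
    """Full cleaning pipeline: blink → quality → velocity → interpolate
    → smooth, with a per-stage removal log."""
    removed = {}
    stage = blink_filter(raw)
    removed["blink"] = stage.n_missing - raw.n_missing
    prev = stage
    stage = quality_filter(stage, params)
    removed["quality"] = stage.n_missing - prev.n_missing
    prev = stage
    stage = velocity_filter(stage, params)
    removed["velocity"] = stage.n_missing - prev.n_missing
    interpolated = interpolate_gaps(stage)
    removed["interpolated"] = stage.n_missing
    smoothed = smooth(interpolated, params)
    # artifact annotations are consumed by cleaning: the output carries
    # repaired diameters, so flags and quality scores no longer apply
    final = replace(
        smoothed,
        blink=np.zeros(smoothed.time_s.size, dtype=bool),
        quality_pct=np.full(smoothed.time_s.size, 100.0),
    )
    return CleanResult(trace=final, removed=removed)
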