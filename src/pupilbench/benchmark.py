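"""Model-versus-measurement benchmarking statistics.

Two separate analyses mirror how prediction accuracy is commonly
assessed in pupillometry:

* **Model error** compares the *absolute* measured diameter, extracted
  as a windowed mean at fixed exposure times (1, 60, 300 s by default),
  against each closed-form model's prediction; summarized as the mean
  and sample SD of (predicted − measured) over subjects.  A constant
  offset shared across conditions can be removed afterwards
  (:func:`offset_correct`).
* **Spectral dependence** tests whether the *baseline-corrected*
  diameter (stimulus minus the mean of the final seconds of the
  preceding re-adaptation anchor) differs between stimuli, via a
  one-way repeated-measures ANOVA with Mauchly's sphericity test,
  Greenhouse–Geisser correction when sphericity is violated, η² effect
  sizes and Bonferroni-corrected pairwise paired t-tests.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from pupilbench.preprocessing import PupilTrace

__all__ = [
    "ExposureDesign",
    "ErrorSummary",
    "PairwiseComparison",
    "RmAnovaResult",
    "baseline_correct",
    "extract_diameter",
    "prediction_error",
    "offset_correct",
    "rm_anova",
]


@dataclass(frozen=True)
class ExposureDesign:
    """Stimulus schedule of a benchmarking session."""

    stimulus_labels: tuple
    exposure_times_s: tuple = (1.0, 60.0, 300.0)
    anchor_label: str = "anchor"
    stimulus_duration_s: float = 300.0
    anchor_duration_s: float = 300.0

    def __post_init__(self):
        object.__setattr__(self, "stimulus_labels", tuple(self.stimulus_labels))
        object.__setattr__(
            self, "exposure_times_s", tuple(float(t) for t in self.exposure_times_s)
        )
        if len(set(self.stimulus_labels)) != len(self.stimulus_labels):
            raise ValueError("stimulus labels must be unique")
        for t in self.exposure_times_s:
            if not (0.0 <= t <= self.stimulus_duration_s):
                raise ValueError(
                    f"exposure time {t}s outside the stimulus duration "
                    f"{self.stimulus_duration_s}s"
                )


@dataclass(frozen=True)
class ErrorSummary:
    """Mean/SD of (predicted − measured) for one model × stimulus × time."""

    model_id: str
    stimulus: str
    exposure_time_s: float
    mean_error_mm: float
    sd_error_mm: float
    n: int

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("need at least one measurement")
        if self.sd_error_mm < 0 or math.isnan(self.mean_error_mm):
            raise ValueError("invalid error summary")


@dataclass(frozen=True)
class PairwiseComparison:
    pair: tuple
    t: float
    p_bonferroni: float
    mean_diff_mm: float


@dataclass(frozen=True)
class RmAnovaResult:
    """One-way within-subject ANOVA with sphericity handling.

    ``f_value`` and the degrees of freedom are Greenhouse–Geisser
    ε-corrected when Mauchly's test rejects sphericity (p < 0.05); the
    uncorrected df are recoverable as ``df1/gg_epsilon`` etc.
    ``eta_sq`` is the classical SS_effect/SS_total; ``eta_sq_partial``
    is SS_effect/(SS_effect + SS_error).
    """

    mauchly_w: float
    mauchly_chi2: float
    mauchly_df: int
    mauchly_p: float
    gg_epsilon: float
    epsilon_applied: bool
    f_value: float
    df1: float
    df2: float
    p_value: float
    eta_sq: float
    eta_sq_partial: float
    pairwise: tuple = field(default_factory=tuple)


def baseline_correct(
    stim_trace: PupilTrace, anchor_trace: PupilTrace, window_s: float = 10.0
) -> PupilTrace:
    """Subtract the anchor baseline from a stimulus trace.

    The baseline is the mean diameter over the final ``window_s``
    seconds of the anchor (re-adaptation) trace; the returned trace is
    ``stim(t) − baseline`` on the unchanged stimulus time axis.
    """
    t_a = anchor_trace.time_s
    span = t_a[-1] - t_a[0]
    if span < window_s:
        raise ValueError(
            f"anchor trace spans {span:.1f}s, shorter than the {window_s}s baseline window"
        )
    sel = t_a >= t_a[-1] - window_s
    window = anchor_trace.diameter_mm[sel]
    if np.all(np.isnan(window)):
        raise ValueError("anchor baseline window contains no present samples")
    baseline = float(np.nanmean(window))
    corrected = stim_trace.diameter_mm - baseline
    # corrected diameters are differences; bypass the absolute-range check
    out = object.__new__(PupilTrace)
    for name, val in (
        ("time_s", stim_trace.time_s),
        ("diameter_mm", corrected),
        ("quality_pct", stim_trace.quality_pct),
        ("blink", stim_trace.blink),
        ("meta", {**stim_trace.meta, "baseline_mm": baseline}),
    ):
        object.__setattr__(out, name, val)
    return out


def extract_diameter(trace: PupilTrace, t_s: float, window_s: float = 1.0) -> float:
    """Mean diameter over a ``window_s`` window centered at ``t_s``.

    Windows that would overrun either end of the trace are shifted to
    stay inside while keeping their width (e.g. a request at the final
    timestamp averages the last ``window_s`` seconds).  Requests more
    than half a window outside the trace raise.
    """
    t = trace.time_s
    step = 1.0 / trace.fs
    t0, t1 = float(t[0]), float(t[-1])
    t_end = t1 + step  # nominal end of the sampled interval
    if t_end - t0 < window_s:
        raise ValueError("trace shorter than the extraction window")
    if not (t0 - window_s / 2.0 <= t_s <= t_end + window_s / 2.0):
        raise ValueError(f"extraction time {t_s}s outside the trace [{t0}, {t1}]s")
    hi = min(max(t_s + window_s / 2.0, t0 + window_s), t_end)
    lo = hi - window_s
    sel = (t >= lo - 1e-9) & (t <= hi + 1e-9)
    vals = trace.diameter_mm[sel]
    if np.all(np.isnan(vals)):
        raise ValueError("extraction window contains no present samples")
    return float(np.nanmean(vals))


def prediction_error(
    predicted_mm: float,
    measured_mm: Sequence[float],
    *,
    model_id: str = "",
    stimulus: str = "",
    exposure_time_s: float = float("nan"),
) -> ErrorSummary:
    """Mean and sample SD (n−1) of (predicted − measured_i)."""
    measured = np.asarray(list(measured_mm), dtype=float)
    if measured.size == 0:
        raise ValueError("empty measurement set")
    errors = predicted_mm - measured
    sd = float(np.std(errors, ddof=1)) if errors.size > 1 else 0.0
    return ErrorSummary(
        model_id=model_id,
        stimulus=stimulus,
        exposure_time_s=exposure_time_s,
        mean_error_mm=float(np.mean(errors)),
        sd_error_mm=sd,
        n=int(errors.size),
    )


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal rounding with ties away from zero (the convention used
    when reporting offset-corrected errors to two decimals; binary
    round-half-even would turn 0.115 into 0.11)."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(f"{value:.12f}").quantize(q, rounding=ROUND_HALF_UP))


def offset_correct(condition_means_mm: Sequence[float]) -> tuple[np.ndarray, float]:
    """Remove the shared constant offset from per-condition mean errors.

    The offset is the unweighted mean of the condition means; returns
    ``(corrected_means, offset)`` with ``corrected_i = mean_i − offset``
    (the corrected values are exactly centered).
    """
    means = np.asarray(list(condition_means_mm), dtype=float)
    if means.size < 2:
        raise ValueError("offset correction needs at least two condition means")
    offset = float(np.mean(means))
    return means - offset, offset


# ---------------------------------------------------------------------------
# repeated-measures ANOVA


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k−1)×k orthonormal basis of the contrast space (rows ⟂ 1)."""
    basis, _ = np.linalg.qr(np.vstack([np.ones(k), np.eye(k)[:-1]]).T)
    c = basis[:, 1:].T
    return c


def rm_anova(
    data: np.ndarray,
    condition_labels: Optional[Sequence[str]] = None,
    *,
    gg_threshold_p: float = 0.05,
) -> RmAnovaResult:
    """One-way within-subject (repeated-measures) ANOVA.

    Parameters
    ----------
    data : (n_subjects, k_conditions) array
        Complete matrix of per-subject measurements (no missing cells).
    condition_labels : sequence of str, optional
        Labels for the pairwise table; defaults to column indices.
    gg_threshold_p : float
        Mauchly p-value below which the Greenhouse–Geisser ε is applied
        to both degrees of freedom.

    Notes
    -----
    Sums of squares follow the definitional decomposition
    ``SS_total = SS_conditions + SS_subjects + SS_error`` of the
    two-way (subject × condition) layout without replication.
    Mauchly's W is computed from the sample covariance of the condition
    columns projected onto an orthonormal contrast basis, with the
    standard χ² approximation.  Greenhouse–Geisser ε comes from the
    eigenvalues of the same projected covariance.  Pairwise paired
    t-tests are Bonferroni-multiplied by the number of pairs.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ValueError("data must be a subjects × conditions matrix")
    n, k = x.shape
    if n < 3 or k < 2:
        raise ValueError("need at least 3 subjects and 2 conditions")
    if np.any(np.isnan(x)):
        raise ValueError("missing cells are not supported (no imputation)")
    labels = (
        tuple(condition_labels)
        if condition_labels is not None
        else tuple(str(j) for j in range(k))
    )
    if len(labels) != k:
        raise ValueError("one label per condition required")

    grand = x.mean()
    cond_means = x.mean(axis=0)
    subj_means = x.mean(axis=1)
    ss_total = float(((x - grand) ** 2).sum())
    ss_cond = float(n * ((cond_means - grand) ** 2).sum())
    ss_subj = float(k * ((subj_means - grand) ** 2).sum())
    ss_err = ss_total - ss_cond - ss_subj

    df1 = k - 1
    df2 = (n - 1) * (k - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    f_value = ms_cond / ms_err

    # sphericity: covariance in the contrast space
    c = _orthonormal_contrasts(k)
    cov = np.cov(x, rowvar=False, ddof=1)
    s = c @ cov @ c.T
    eig = np.linalg.eigvalsh(s)
    eig = np.clip(eig, 0.0, None)
    p_dim = k - 1
    if k == 2:
        w = 1.0
        chi2_stat = 0.0
        mauchly_df = 0
        mauchly_p = 1.0
        epsilon = 1.0
    else:
        mean_eig = eig.mean()
        w = float(np.prod(eig) / mean_eig**p_dim) if mean_eig > 0 else 0.0
        dd = 1.0 - (2.0 * p_dim**2 + p_dim + 2.0) / (6.0 * p_dim * (n - 1))
        chi2_stat = -(n - 1) * dd * math.log(max(w, np.finfo(float).tiny))
        mauchly_df = int(p_dim * (p_dim + 1) / 2 - 1)
        mauchly_p = float(stats.chi2.sf(chi2_stat, mauchly_df))
        epsilon = float(eig.sum() ** 2 / (p_dim * (eig**2).sum()))
        epsilon = min(max(epsilon, 1.0 / p_dim), 1.0)

    apply_eps = mauchly_p < gg_threshold_p and epsilon < 1.0
    eff_df1 = df1 * epsilon if apply_eps else float(df1)
    eff_df2 = df2 * epsilon if apply_eps else float(df2)
    p_value = float(stats.f.sf(f_value, eff_df1, eff_df2))

    pairs = []
    combos = list(itertools.combinations(range(k), 2))
    for i, j in combos:
        t_stat, p_raw = stats.ttest_rel(x[:, i], x[:, j])
        pairs.append(
            PairwiseComparison(
                pair=(labels[i], labels[j]),
                t=float(t_stat),
                p_bonferroni=min(float(p_raw) * len(combos), 1.0),
                mean_diff_mm=float((x[:, i] - x[:, j]).mean()),
            )
        )

    return RmAnovaResult(
        mauchly_w=w,
        mauchly_chi2=chi2_stat,
        mauchly_df=mauchly_df,
        mauchly_p=mauchly_p,
        gg_epsilon=epsilon,
        epsilon_applied=apply_eps,
        f_value=f_value,
        df1=eff_df1,
        df2=eff_df2,
        p_value=p_value,
        eta_sq=ss_cond / ss_total,
        eta_sq_partial=ss_cond / (ss_cond + ss_err),
        pairwise=tuple(pairs),
    )
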