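"""CSV/YAML interchange and full-pipeline orchestration.

Formats
-------
Trace CSV
    header ``time_s,diameter_mm,quality_pct,blink``; missing diameters
    are empty fields; ``blink`` is 0/1.  Round-trips losslessly.
Spectrum CSV
    header ``wavelength_nm,radiance_W_m2_sr_nm``; read back resampled to
    the common 1 nm grid.
Design YAML
    the stimulus schedule, viewing conditions, model list and
    preprocessing overrides for a benchmark run (see
    :class:`DesignConfig`).

:func:`run_full_benchmark` ties the stages together: clean every trace,
baseline-correct against its anchor, extract diameters at the design's
exposure times, summarize per-model prediction errors on the absolute
diameters and run the repeated-measures ANOVA on the baseline-corrected
ones.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from pupilbench.benchmark import (
    ErrorSummary,
    ExposureDesign,
    RmAnovaResult,
    baseline_correct,
    extract_diameter,
    prediction_error,
    rm_anova,
)
from pupilbench.colorimetry import Spectrum, StimulusMetrics, stimulus_metrics
from pupilbench.models import FieldGeometry, ViewingConditions, predict_diameter
from pupilbench.preprocessing import PreprocessParams, PupilTrace, clean_trace
from pupilbench.synthetic import CohortMember

__all__ = [
    "TraceParseError",
    "read_trace",
    "write_trace",
    "read_spectrum",
    "write_spectrum",
    "DesignConfig",
    "load_design",
    "save_design",
    "BenchmarkReport",
    "benchmark_cohort",
    "run_full_benchmark",
]

_TRACE_COLUMNS = ["time_s", "diameter_mm", "quality_pct", "blink"]
_SPECTRUM_COLUMNS = ["wavelength_nm", "radiance_W_m2_sr_nm"]


class TraceParseError(ValueError):
    """Malformed trace or spectrum file (message carries the line number)."""


def read_trace(path) -> PupilTrace:
    """Read a trace CSV; raises :class:`TraceParseError` with the
    offending line number on malformed input."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise TraceParseError(
            f"{path.name}: header line 1 missing column(s) {', '.join(missing)}"
        )
    t = df["time_s"].to_numpy(dtype=float)
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        raise TraceParseError(
            f"{path.name}: non-monotone time at line {int(bad[0]) + 3}"
        )
    try:
        return PupilTrace(
            time_s=t,
            diameter_mm=df["diameter_mm"].to_numpy(dtype=float),
            quality_pct=df["quality_pct"].to_numpy(dtype=float),
            blink=df["blink"].to_numpy().astype(bool),
            meta={"source": str(path)},
        )
    except ValueError as exc:
        raise TraceParseError(f"{path.name}: {exc}") from exc


def write_trace(trace: PupilTrace, path) -> None:
    df = pd.DataFrame(
        {
            "time_s": trace.time_s,
            "diameter_mm": trace.diameter_mm,
            "quality_pct": trace.quality_pct,
            "blink": trace.blink.astype(int),
        }
    )
    df.to_csv(path, index=False, float_format="%.10g")


def read_spectrum(path) -> Spectrum:
    """Read a spectrum CSV, validated and resampled to the 1 nm grid."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _SPECTRUM_COLUMNS if c not in df.columns]
    if missing:
        raise TraceParseError(
            f"{path.name}: header line 1 missing column(s) {', '.join(missing)}"
        )
    wl = df["wavelength_nm"].to_numpy(dtype=float)
    ra = df["radiance_W_m2_sr_nm"].to_numpy(dtype=float)
    if wl.size < 2:
        raise TraceParseError(f"{path.name}: need at least two samples to integrate")
    bad = np.flatnonzero(np.diff(wl) <= 0)
    if bad.size:
        raise TraceParseError(
            f"{path.name}: unsorted wavelengths at line {int(bad[0]) + 3}"
        )
    neg = np.flatnonzero(ra < 0)
    if neg.size:
        raise TraceParseError(
            f"{path.name}: negative radiance at line {int(neg[0]) + 2}"
        )
    try:
        return Spectrum.from_samples(wl, ra)
    except ValueError as exc:
        raise TraceParseError(f"{path.name}: {exc}") from exc


def write_spectrum(spec: Spectrum, path) -> None:
    pd.DataFrame(
        {
            "wavelength_nm": spec.wavelengths_nm,
            "radiance_W_m2_sr_nm": spec.radiance,
        }
    ).to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# design configuration


@dataclass(frozen=True)
class StimulusSpec:
    """One stimulus in a design: a label plus either a spectrum file or
    an explicit luminance (spectrum-free models only need the latter)."""

    label: str
    spectrum_csv: Optional[str] = None
    luminance_cdm2: Optional[float] = None
    anchor: Optional[str] = "anchor"  # anchor label, or None for no baseline


@dataclass(frozen=True)
class DesignConfig:
    """Declarative description of a benchmark run."""

    stimuli: tuple
    models: tuple = ("crawford", "de_groot_gebhard", "watson_yellott")
    exposure_times_s: tuple = (1.0, 60.0, 300.0)
    field_kind: str = "circular"
    field_sizes_deg: tuple = (53.13,)
    field_conversion: str = "circle_area"
    age_years: float = 22.2
    eyes: int = 2
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    baseline_window_s: float = 10.0
    extraction_window_s: float = 1.0

    def __post_init__(self):
        labels = [s.label for s in self.stimuli]
        if len(set(labels)) != len(labels):
            raise ValueError("stimulus labels must be unique")

    @property
    def field(self) -> FieldGeometry:
        return FieldGeometry(
            self.field_kind,
            self.field_sizes_deg,
            self.field_conversion,
            allow_flat_large_field=True,
        )

    def viewing_conditions(self, luminance_cdm2: float) -> ViewingConditions:
        return ViewingConditions(
            luminance_cdm2=luminance_cdm2,
            field=self.field,
            age_years=self.age_years,
            eyes=self.eyes,
        )


def load_design(path) -> DesignConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    stimuli = tuple(StimulusSpec(**s) for s in raw.pop("stimuli"))
    pp = raw.pop("preprocess", None)
    kwargs = {k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()}
    if pp is not None:
        kwargs["preprocess"] = PreprocessParams(**pp)
    return DesignConfig(stimuli=stimuli, **kwargs)


def save_design(config: DesignConfig, path) -> None:
    data = dataclasses.asdict(config)
    data["stimuli"] = [dataclasses.asdict(s) for s in config.stimuli]
    data["preprocess"] = dataclasses.asdict(config.preprocess)
    for key in ("models", "exposure_times_s", "field_sizes_deg"):
        data[key] = list(data[key])
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# orchestration


@dataclass(frozen=True)
class BenchmarkReport:
    """Full benchmark output: per-model error summaries and per-exposure
    ANOVA results, with the parameters that produced them."""

    error_summaries: tuple  # of ErrorSummary
    anova: dict  # exposure_time_s -> RmAnovaResult
    predictions: dict  # model -> {stimulus -> predicted mm}
    parameters: dict

    def errors_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(e) for e in self.error_summaries])

    def to_json_dict(self) -> dict:
        return {
            "parameters": self.parameters,
            "predictions": self.predictions,
            "error_summaries": [dataclasses.asdict(e) for e in self.error_summaries],
            "anova": {
                str(t): _anova_dict(res) for t, res in self.anova.items()
            },
        }


def _anova_dict(res: RmAnovaResult) -> dict:
    d = dataclasses.asdict(res)
    d["pairwise"] = [dataclasses.asdict(p) for p in res.pairwise]
    return d


def benchmark_cohort(
    members: Sequence[CohortMember],
    stimuli: dict,
    config: DesignConfig,
) -> BenchmarkReport:
    """Benchmark an in-memory cohort.

    Parameters
    ----------
    members : sequence of CohortMember
        Subjects with raw stimulus and anchor traces.
    stimuli : dict label -> StimulusMetrics
        Spectral metrics of each stimulus (supplies the luminance the
        models are evaluated at).
    config : DesignConfig
        Field geometry, observer parameters, model list, exposure times
        and preprocessing parameters.
    """
    labels = [s.label for s in config.stimuli]
    times = config.exposure_times_s
    absolute = {lbl: {t: [] for t in times} for lbl in labels}
    corrected = {lbl: {t: [] for t in times} for lbl in labels}

    for member in members:
        for lbl in labels:
            cleaned = clean_trace(member.traces[lbl], config.preprocess).trace
            anchor_clean = clean_trace(member.anchors[lbl], config.preprocess).trace
            bc = baseline_correct(cleaned, anchor_clean, config.baseline_window_s)
            for t in times:
                absolute[lbl][t].append(
                    extract_diameter(cleaned, t, config.extraction_window_s)
                )
                corrected[lbl][t].append(
                    extract_diameter(bc, t, config.extraction_window_s)
                )

    predictions: dict = {}
    summaries: list[ErrorSummary] = []
    for model in config.models:
        predictions[model] = {}
        for lbl in labels:
            cond = config.viewing_conditions(stimuli[lbl].luminance_cdm2)
            pred = predict_diameter(model, cond).diameter_mm
            predictions[model][lbl] = pred
            for t in times:
                summaries.append(
                    prediction_error(
                        pred,
                        absolute[lbl][t],
                        model_id=model,
                        stimulus=lbl,
                        exposure_time_s=t,
                    )
                )

    anova = {}
    if len(labels) >= 2 and len(members) >= 3:
        for t in times:
            matrix = np.column_stack([corrected[lbl][t] for lbl in labels])
            anova[t] = rm_anova(matrix, labels)

    return BenchmarkReport(
        error_summaries=tuple(summaries),
        anova=anova,
        predictions=predictions,
        parameters={
            "models": list(config.models),
            "exposure_times_s": list(times),
            "n_subjects": len(members),
            "age_years": config.age_years,
            "eyes": config.eyes,
            "field": {
                "kind": config.field_kind,
                "sizes_deg": list(config.field_sizes_deg),
                "conversion": config.field_conversion,
            },
            "baseline_window_s": config.baseline_window_s,
            "extraction_window_s": config.extraction_window_s,
        },
    )


def write_cohort(
    members: Sequence[CohortMember],
    spectra: dict,
    out_dir,
    *,
    seed: Optional[int] = None,
) -> Path:
    """Write a simulated cohort to disk: per-presentation trace CSVs,
    stimulus spectrum CSVs, and a manifest JSON carrying ground truth.

    Returns the manifest path; ``run_full_benchmark(manifest=...)``
    consumes it.
    """
    out = Path(out_dir)
    (out / "traces").mkdir(parents=True, exist_ok=True)
    (out / "spectra").mkdir(exist_ok=True)
    manifest = {"seed": seed, "spectra": {}, "subjects": []}
    for lbl, spec in spectra.items():
        rel = f"spectra/{lbl}.csv"
        write_spectrum(spec, out / rel)
        manifest["spectra"][lbl] = rel
    for member in members:
        entry = {"id": member.subject_id, "traces": {}, "anchors": {}, "truth": {}}
        for lbl, trace in member.traces.items():
            rel = f"traces/{member.subject_id}_{lbl}.csv"
            write_trace(trace, out / rel)
            entry["traces"][lbl] = rel
            rel_a = f"traces/{member.subject_id}_{lbl}_anchor.csv"
            write_trace(member.anchors[lbl], out / rel_a)
            entry["anchors"][lbl] = rel_a
            truth = member.truths.get(lbl)
            if truth is not None:
                entry["truth"][lbl] = {"steady_state_mm": truth.steady_state_mm}
        manifest["subjects"].append(entry)
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest_path


def _load_members_from_manifest(manifest_path) -> tuple[list[CohortMember], dict]:
    """Rebuild a cohort (traces + anchors) and its stimulus metrics from
    a ``simulate`` manifest."""
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    root = manifest_path.parent
    stimuli = {}
    for lbl, rel in manifest["spectra"].items():
        stimuli[lbl] = stimulus_metrics(read_spectrum(root / rel))
    members = []
    for subj in manifest["subjects"]:
        traces = {lbl: read_trace(root / rel) for lbl, rel in subj["traces"].items()}
        anchors = {lbl: read_trace(root / rel) for lbl, rel in subj["anchors"].items()}
        members.append(
            CohortMember(
                subject_id=subj["id"],
                params=None,
                traces=traces,
                anchors=anchors,
                truths={},
            )
        )
    return members, stimuli


def run_full_benchmark(
    config: DesignConfig,
    *,
    manifest: Optional[str] = None,
    members: Optional[Sequence[CohortMember]] = None,
    stimuli: Optional[dict] = None,
    out_dir: Optional[str] = None,
) -> BenchmarkReport:
    """Run the complete pipeline and (optionally) write the report.

    Input is either a ``simulate`` manifest on disk or an in-memory
    cohort with its stimulus metrics.  Writes ``report.json`` and
    ``error_summaries.csv`` into ``out_dir`` when given.  Deterministic:
    identical inputs produce identical reports.
    """
    if manifest is not None:
        members, stimuli = _load_members_from_manifest(manifest)
    if members is None or stimuli is None:
        raise ValueError("provide a manifest path or members + stimuli")
    report = benchmark_cohort(members, stimuli, config)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report.to_json_dict(), fh, indent=2)
        report.errors_frame().to_csv(out / "error_summaries.csv", index=False)
    return report
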