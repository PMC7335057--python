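"""Reference study conditions shipped as package defaults.

The default benchmark emulates a two-session constant-luminance
pupillometry protocol:

* **chromatic session** — four narrowband LED stimuli (450, 530, 610,
  660 nm) at 100 cd/m², group mean observer age 22.2 y;
* **polychromatic session** — three white mixtures on the Planckian
  locus (~2000, ~5000, ~10000 K) at 99.8 cd/m², group mean age 21.95 y;
* both sessions: binocular viewing of a 700 × 700 mm adaptation field
  at 700 mm distance — a 53.13° visual angle, represented as a circular
  field converted to deg² with the flat π/4·D² rule (the convention
  matched to the published worked examples; the exact spherical-cap
  area differs by ≈2% at this size); 300 s presentations separated by a
  5500 K anchor at ~200 cd/m²; diameters extracted at 1, 60 and 300 s.
"""

from __future__ import annotations

import math

from pupilbench.colorimetry import Spectrum, luminance
from pupilbench.io import DesignConfig, StimulusSpec
from pupilbench.models import FieldGeometry, ViewingConditions
from pupilbench.synthetic import default_channels, mix_spectrum, solve_weights

__all__ = [
    "FIELD_DIAMETER_DEG",
    "CHROMATIC_LUMINANCE_CDM2",
    "POLYCHROMATIC_LUMINANCE_CDM2",
    "ANCHOR_LUMINANCE_CDM2",
    "CHROMATIC_MEAN_AGE_Y",
    "POLYCHROMATIC_MEAN_AGE_Y",
    "INDIVIDUAL_AGE_Y",
    "study_field",
    "study_conditions",
    "default_study_spectra",
    "default_design",
]

#: Visual angle of a 700 mm square field viewed at 700 mm: 2·atan(0.5).
FIELD_DIAMETER_DEG = 2.0 * math.degrees(math.atan(0.5))  # 53.130...

CHROMATIC_LUMINANCE_CDM2 = 100.0
POLYCHROMATIC_LUMINANCE_CDM2 = 99.8
ANCHOR_LUMINANCE_CDM2 = 200.0
CHROMATIC_MEAN_AGE_Y = 22.2
POLYCHROMATIC_MEAN_AGE_Y = 21.95
INDIVIDUAL_AGE_Y = 33.0

_CHROMATIC_PEAKS_NM = (450, 530, 610, 660)
_POLYCHROMATIC_CCTS_K = (2000, 5000, 10000)
_ANCHOR_CCT_K = 5500


def study_field() -> FieldGeometry:
    """The 53.13° circular-equivalent adaptation field, flat-circle
    conversion (benchmark default)."""
    return FieldGeometry(
        "circular",
        (FIELD_DIAMETER_DEG,),
        "circle_area",
        allow_flat_large_field=True,
    )


def study_conditions(
    session: str = "chromatic", age_years: float | None = None
) -> ViewingConditions:
    """Viewing conditions of one session ('chromatic'/'polychromatic'),
    optionally overriding the group mean age (e.g. for the single
    in-depth observer)."""
    if session == "chromatic":
        lum, age = CHROMATIC_LUMINANCE_CDM2, CHROMATIC_MEAN_AGE_Y
    elif session == "polychromatic":
        lum, age = POLYCHROMATIC_LUMINANCE_CDM2, POLYCHROMATIC_MEAN_AGE_Y
    else:
        raise ValueError("session must be 'chromatic' or 'polychromatic'")
    return ViewingConditions(
        luminance_cdm2=lum,
        field=study_field(),
        age_years=age if age_years is None else age_years,
        eyes=2,
    )


def default_study_spectra() -> dict:
    """Label → Spectrum of the seven stimuli plus the anchor.

    Chromatic stimuli are single channels scaled to 100 cd/m²;
    polychromatic stimuli are 15-channel mixtures solved onto the
    Planckian locus at 99.8 cd/m²; the anchor is the 5500 K mixture at
    200 cd/m².
    """
    channels = default_channels()
    spectra: dict[str, Spectrum] = {}
    for peak in _CHROMATIC_PEAKS_NM:
        idx = next(
            i for i, ch in enumerate(channels)
            if ch.kind == "narrowband" and ch.peak_nm == peak
        )
        weights = [0.0] * len(channels)
        weights[idx] = 1.0
        spec = mix_spectrum(channels, weights)
        spectra[f"led_{peak}nm"] = spec.scaled(
            CHROMATIC_LUMINANCE_CDM2 / luminance(spec)
        )
    for cct_k in _POLYCHROMATIC_CCTS_K:
        w = solve_weights(
            channels, luminance_cdm2=POLYCHROMATIC_LUMINANCE_CDM2, cct_K=cct_k
        )
        spectra[f"planck_{cct_k}K"] = mix_spectrum(channels, w)
    w = solve_weights(channels, luminance_cdm2=ANCHOR_LUMINANCE_CDM2,
                      cct_K=_ANCHOR_CCT_K)
    spectra["anchor"] = mix_spectrum(channels, w)
    return spectra


def default_design() -> DesignConfig:
    """DesignConfig covering all seven stimuli of the default study."""
    labels = [f"led_{p}nm" for p in _CHROMATIC_PEAKS_NM] + [
        f"planck_{t}K" for t in _POLYCHROMATIC_CCTS_K
    ]
    return DesignConfig(
        stimuli=tuple(StimulusSpec(label=lbl) for lbl in labels),
        age_years=CHROMATIC_MEAN_AGE_Y,
        eyes=2,
        field_kind="circular",
        field_sizes_deg=(FIELD_DIAMETER_DEG,),
        field_conversion="circle_area",
    )
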