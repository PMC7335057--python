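"""Closed-form pupil-diameter models driven by photopic luminance.

Eight empirical formulas from the pupillometry literature predict the
steady-state pupil diameter of an adapted observer from the adapting
luminance ``L`` (cd/m²), and — for the later models — from the angular
size of the adapting field, the observer's age, and the number of
exposed eyes:

* Holladay (1926)            ``D = 7·exp(−0.1007·L^0.4)``
* Crawford (1936)            ``D = 5 − 2.2·tanh(0.61151 + 0.447·log10 L)``
* Moon & Spencer (1944)      ``D = 4.9 − 3·tanh(0.4·log10 L)``
* De Groot & Gebhard (1952)  ``D = 7.175·exp(−0.00092·(7.597 + log10 L)³)``
* Stanley & Davies (1995)    ``D = 7.75 − 5.75·q/(q+2)``, ``q = (L·α/846)^0.41``
* Barten (1999)              ``D = 5 − 3·tanh(0.4·log10(L·α/40²))``
* Blackie & Howland (1999)   ``D = 5.697 − 0.658·log10 L + 0.07·(log10 L)²``
* Watson & Yellott (2012)    unified formula: Stanley & Davies with a
  monocular attenuation factor ``e`` on the effective corneal flux
  (``D_SDW``), then a linear age correction around the reference age
  ``y₀ = 28.58`` years.

``α`` is the adapting-field area in square degrees.  Conversions from
angular extents to deg² live in :func:`field_to_deg2`; for wide fields
(> 15° diameter) the exact spherical-cap area should be used rather
than the flat-field product, since the flat approximation inflates the
solid angle.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field
from typing import Callable, Optional

__all__ = [
    "FieldGeometry",
    "ViewingConditions",
    "ModelPrediction",
    "MODEL_IDS",
    "field_to_deg2",
    "predict_diameter",
    "InvalidGeometryError",
    "MissingParameterError",
    "REFERENCE_AGE_YEARS",
]

#: Reference age of the Watson & Yellott age correction (years).
REFERENCE_AGE_YEARS = 28.58

#: Degrees² in a full sphere divided by 2π: the spherical-cap conversion
#: constant, area(deg²) = 6566·π·(1 − cos(D·π/360)) for cap diameter D.
_CAP_CONSTANT = 6566.0

_DEG2_PER_SPHERE_CHECK = 4 * math.pi * (180.0 / math.pi) ** 2  # ≈ 41252.96


class InvalidGeometryError(ValueError):
    """Adaptation-field geometry is unphysical (angle ≤ 0 or ≥ 180°)."""


class MissingParameterError(ValueError):
    """A model requires a parameter absent from the viewing conditions."""


@dataclass(frozen=True)
class FieldGeometry:
    """Angular geometry of the adapting field.

    Parameters
    ----------
    kind : {"rectangular", "circular"}
    sizes : tuple of float
        Angular extents in degrees: ``(width, height)`` for rectangular,
        ``(diameter,)`` for circular fields.
    conversion : {"product", "circle_area", "spherical_cap", "legacy_toolbox"}
        Rule mapping the extents to a deg² area.  ``spherical_cap`` is the
        exact solid-angle area and is required for extents above 15°
        unless ``allow_flat_large_field`` is set.
    allow_flat_large_field : bool
        Explicit override permitting a flat-field conversion on a wide
        field (emits a warning instead of raising).
    """

    kind: str
    sizes: tuple
    conversion: str = "circle_area"
    allow_flat_large_field: bool = False

    def __post_init__(self):
        if self.kind not in ("rectangular", "circular"):
            raise InvalidGeometryError(f"unknown field kind {self.kind!r}")
        sizes = tuple(float(s) for s in self.sizes)
        object.__setattr__(self, "sizes", sizes)
        n_expected = 2 if self.kind == "rectangular" else 1
        if len(sizes) != n_expected:
            raise InvalidGeometryError(
                f"{self.kind} field needs {n_expected} angular extent(s), got {len(sizes)}"
            )
        for s in sizes:
            if not (0.0 < s < 180.0) or not math.isfinite(s):
                raise InvalidGeometryError(
                    f"angular extent must lie in (0, 180) degrees, got {s}"
                )
        if self.conversion not in (
            "product",
            "circle_area",
            "spherical_cap",
            "legacy_toolbox",
        ):
            raise InvalidGeometryError(f"unknown conversion {self.conversion!r}")

    @property
    def equivalent_diameter_deg(self) -> float:
        """Diameter of the circle with the same flat angular area."""
        if self.kind == "circular":
            return self.sizes[0]
        ax, ay = self.sizes
        return 2.0 * math.sqrt(ax * ay / math.pi)

    @property
    def max_extent_deg(self) -> float:
        return max(self.sizes)


def field_to_deg2(field: FieldGeometry) -> float:
    """Convert an adapting-field geometry to an area in square degrees.

    Conversion rules
    ----------------
    ``product``
        ``α = αx·αy`` — Barten's rectangular rule (flat field).
    ``circle_area``
        ``α = π/4·D²`` — Barten's circular rule (flat field).
    ``spherical_cap``
        ``α = 6566·π·(1 − cos(D·π/360))`` — exact solid-angle area of the
        spherical cap subtended by a circular field of diameter ``D``
        (the circular-equivalent diameter for rectangular fields).
        Recommended above 15°.
    ``legacy_toolbox``
        ``α = (D/2)·π`` — an approximation found in circulated pupil
        toolboxes; dimensionally wrong and badly off for large fields.
        Kept only to reproduce its output; always warns.
    """
    conv = field.conversion
    if conv != "spherical_cap" and field.max_extent_deg > 15.0:
        msg = (
            f"flat-field conversion {conv!r} on a {field.max_extent_deg:.1f}° field: "
            "the spherical-cap formula is recommended above 15°"
        )
        if field.allow_flat_large_field:
            warnings.warn(msg, stacklevel=2)
        else:
            raise InvalidGeometryError(
                msg + " (set allow_flat_large_field=True to override)"
            )

    if conv == "product":
        if field.kind != "rectangular":
            raise InvalidGeometryError("product conversion needs a rectangular field")
        ax, ay = field.sizes
        return ax * ay
    if conv == "circle_area":
        d = field.equivalent_diameter_deg
        return math.pi / 4.0 * d * d
    if conv == "spherical_cap":
        d = field.equivalent_diameter_deg
        return _CAP_CONSTANT * math.pi * (1.0 - math.cos(d * math.pi / 360.0))
    # legacy_toolbox
    warnings.warn(
        "legacy_toolbox conversion (α/2)·π is a documented pitfall; "
        "it is not an area and diverges from the exact value for large fields",
        stacklevel=2,
    )
    return (field.equivalent_diameter_deg / 2.0) * math.pi


@dataclass(frozen=True)
class ViewingConditions:
    """Photometric and observer parameters entering the pupil models.

    Parameters
    ----------
    luminance_cdm2 : float
        Adapting luminance ``L`` in cd/m²; must be positive.
    field : FieldGeometry, optional
        Needed by the field-size-aware models (Stanley & Davies, Barten,
        Watson & Yellott).
    age_years : float, optional
        Observer age ``y``; the Watson & Yellott age correction was fit
        on observers aged 17–83, so ages outside that range warn.
    eyes : int, optional
        Number of exposed eyes, 1 or 2.  Monocular viewing attenuates the
        effective corneal flux by ``e = 0.1``; binocular ``e = 1``.
    """

    luminance_cdm2: float
    field: Optional[FieldGeometry] = None
    age_years: Optional[float] = None
    eyes: Optional[int] = None

    def __post_init__(self):
        if not (self.luminance_cdm2 > 0.0) or not math.isfinite(self.luminance_cdm2):
            raise ValueError(f"luminance must be positive, got {self.luminance_cdm2}")
        if self.age_years is not None:
            y = float(self.age_years)
            if not (16.0 <= y <= 90.0):
                raise ValueError(f"age {y} outside supported range [16, 90] years")
            if not (17.0 <= y <= 83.0):
                warnings.warn(
                    f"age {y} y outside the 17–83 y range of the age-correction "
                    "data; extrapolating",
                    stacklevel=2,
                )
        if self.eyes is not None and self.eyes not in (1, 2):
            raise ValueError(f"eyes must be 1 or 2, got {self.eyes}")

    @property
    def monocular_factor(self) -> float:
        """``e``: 0.1 for one exposed eye, 1 for two."""
        if self.eyes is None:
            raise MissingParameterError("number of exposed eyes not specified")
        return 0.1 if self.eyes == 1 else 1.0

    @property
    def alpha_deg2(self) -> float:
        if self.field is None:
            raise MissingParameterError("adaptation-field geometry not specified")
        return field_to_deg2(self.field)


@dataclass(frozen=True)
class ModelPrediction:
    """A pupil-diameter prediction in mm, with the pre-age-correction
    Stanley–Davies–Watson diameter ``D_SDW`` exposed for the unified model."""

    model_id: str
    diameter_mm: float
    intermediate_dsdw_mm: Optional[float] = None

    def __post_init__(self):
        if not (0.0 < self.diameter_mm < 10.0):
            raise ValueError(
                f"predicted diameter {self.diameter_mm} mm outside (0, 10) mm"
            )


def _holladay(c: ViewingConditions) -> float:
    return 7.0 * math.exp(-0.1007 * c.luminance_cdm2**0.4)


def _crawford(c: ViewingConditions) -> float:
    return 5.0 - 2.2 * math.tanh(0.61151 + 0.447 * math.log10(c.luminance_cdm2))


def _moon_spencer(c: ViewingConditions) -> float:
    return 4.9 - 3.0 * math.tanh(0.4 * math.log10(c.luminance_cdm2))


def _de_groot_gebhard(c: ViewingConditions) -> float:
    return 7.175 * math.exp(-0.00092 * (7.597 + math.log10(c.luminance_cdm2)) ** 3)


def _stanley_davies_core(flux: float) -> float:
    # flux = L·α·e / 846 (e = 1 for the plain Stanley & Davies model)
    q = flux**0.41
    return 7.75 - 5.75 * q / (q + 2.0)


def _stanley_davies(c: ViewingConditions) -> float:
    return _stanley_davies_core(c.luminance_cdm2 * c.alpha_deg2 / 846.0)


def _barten(c: ViewingConditions) -> float:
    return 5.0 - 3.0 * math.tanh(
        0.4 * math.log10(c.luminance_cdm2 * c.alpha_deg2 / 40.0**2)
    )


def _blackie_howland(c: ViewingConditions) -> float:
    if c.luminance_cdm2 > 10.0:
        warnings.warn(
            "Blackie & Howland was fit on data up to 10 cd/m²; "
            f"evaluating outside its stated validity at L={c.luminance_cdm2} cd/m²",
            stacklevel=3,
        )
    lg = math.log10(c.luminance_cdm2)
    return 5.697 - 0.658 * lg + 0.07 * lg * lg


def watson_yellott_dsdw(c: ViewingConditions) -> float:
    """``D_SDW``: Stanley & Davies evaluated on the monocularly attenuated
    effective flux ``L·α·e/846`` (mm)."""
    return _stanley_davies_core(
        c.luminance_cdm2 * c.alpha_deg2 * c.monocular_factor / 846.0
    )


def _watson_yellott(c: ViewingConditions) -> float:
    if c.age_years is None:
        raise MissingParameterError("Watson & Yellott requires the observer age")
    d_sdw = watson_yellott_dsdw(c)
    return d_sdw + (c.age_years - REFERENCE_AGE_YEARS) * (
        0.02132 - 0.009562 * d_sdw
    )


_NEEDS_FIELD = frozenset({"stanley_davies", "barten", "watson_yellott"})
_NEEDS_AGE_EYES = frozenset({"watson_yellott"})

_MODELS: dict[str, Callable[[ViewingConditions], float]] = {
    "holladay": _holladay,
    "crawford": _crawford,
    "moon_spencer": _moon_spencer,
    "de_groot_gebhard": _de_groot_gebhard,
    "stanley_davies": _stanley_davies,
    "barten": _barten,
    "blackie_howland": _blackie_howland,
    "watson_yellott": _watson_yellott,
}

#: Identifiers of the eight supported models.
MODEL_IDS = tuple(_MODELS)


def predict_diameter(model_id: str, cond: ViewingConditions) -> ModelPrediction:
    """Evaluate one pupil model under the given viewing conditions.

    Returns the diameter in mm at full floating precision (round only at
    presentation).  Models needing the adapting-field size raise
    :class:`MissingParameterError` when no :class:`FieldGeometry` is
    given; Watson & Yellott additionally requires ``age_years`` and
    ``eyes``.
    """
    key = model_id.lower().replace("-", "_").replace(" ", "_")
    if key not in _MODELS:
        raise KeyError(
            f"unknown model {model_id!r}; choose from {', '.join(MODEL_IDS)}"
        )
    if key in _NEEDS_FIELD and cond.field is None:
        raise MissingParameterError(f"{key} requires an adaptation-field geometry")
    if key in _NEEDS_AGE_EYES:
        if cond.age_years is None:
            raise MissingParameterError(f"{key} requires the observer age")
        if cond.eyes is None:
            raise MissingParameterError(f"{key} requires the number of exposed eyes")
    diameter = _MODELS[key](cond)
    dsdw = watson_yellott_dsdw(cond) if key == "watson_yellott" else None
    return ModelPrediction(model_id=key, diameter_mm=diameter, intermediate_dsdw_mm=dsdw)
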