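"""Allometric weight-normalisation of echocardiographic measurements.

Linear cardiac dimensions grow with body size.  Dividing a raw dimension
(cm) by body weight (kg) raised to a parameter-specific exponent *b*
removes that dependence::

    normalised value = value_cm / weight_kg ** b

The exponents are fitted constants from the allometric-scaling literature
and are **not** shipped with this package; they must be supplied as
configuration (a flat JSON map parameter -> b).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from .errors import ConfigurationError, InvalidInputError
from .params import Group, Parameter

#: Upper body weight (kg) validated by the reference data; heavier animals
#: are normalised anyway but the profile carries a warning flag.
WEIGHT_VALIDATED_MAX_KG = 20.0


def _check_positive(name: str, value: float) -> None:
    if not math.isfinite(value) or value <= 0:
        raise InvalidInputError(f"{name} must be a positive finite number, got {value!r}")


@dataclass(frozen=True)
class MeasurementRecord:
    """Raw echocardiographic values (cm) for one animal.

    ``values`` maps :class:`Parameter` to the absolute measurement in cm;
    parameters whose images were unusable are simply absent.
    """

    subject_id: str
    weight_kg: float
    group: Group
    values: Mapping[Parameter, float]

    def __post_init__(self) -> None:
        _check_positive("weight_kg", self.weight_kg)
        if not isinstance(self.group, Group):
            raise InvalidInputError(f"group must be a Group member, got {self.group!r}")
        for param, value in self.values.items():
            if not isinstance(param, Parameter):
                raise InvalidInputError(f"values key {param!r} is not a Parameter")
            _check_positive(f"values[{param.value}]", value)


@dataclass(frozen=True)
class AllometricExponents:
    """The allometric exponent b for each of the seven parameters."""

    by_parameter: Mapping[Parameter, float]

    def __post_init__(self) -> None:
        missing = [p.value for p in Parameter if p not in self.by_parameter]
        if missing:
            raise ConfigurationError(f"missing allometric exponent(s) for: {', '.join(missing)}")
        for param, b in self.by_parameter.items():
            if not math.isfinite(b):
                raise ConfigurationError(f"exponent for {param.value} is not finite: {b!r}")

    def __getitem__(self, param: Parameter) -> float:
        return self.by_parameter[param]

    @classmethod
    def from_json(cls, path: str | Path) -> "AllometricExponents":
        """Load a flat ``{"AID": 0.33, ...}`` map (raw or normalised keys)."""
        raw = json.loads(Path(path).read_text())
        try:
            mapping = {Parameter.from_any_name(k): float(v) for k, v in raw.items()}
        except ValueError as exc:
            raise ConfigurationError(f"bad exponent file {path}: {exc}") from exc
        return cls(mapping)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({p.value: self.by_parameter[p] for p in Parameter}, indent=1) + "\n"
        )


@dataclass(frozen=True)
class NormalizedProfile:
    """Weight-normalised values for one animal (dimensionless units).

    ``weight_warning`` is set when the animal is heavier than the weight
    range the reference grid was validated on (> 20 kg); the values are
    still computed.
    """

    subject_id: str
    values: Mapping[Parameter, float]
    weight_warning: bool = field(default=False)


def normalize_value(value_cm: float, weight_kg: float, b: float) -> float:
    """Return ``value_cm / weight_kg ** b``.

    Strictly positive; strictly decreasing in weight when ``b > 0``.
    """
    _check_positive("value_cm", value_cm)
    _check_positive("weight_kg", weight_kg)
    if not math.isfinite(b):
        raise InvalidInputError(f"b must be finite, got {b!r}")
    return value_cm / weight_kg**b


def denormalize_value(value_n: float, weight_kg: float, b: float) -> float:
    """Inverse of :func:`normalize_value` (used by the synthetic generator)."""
    _check_positive("value_n", value_n)
    _check_positive("weight_kg", weight_kg)
    if not math.isfinite(b):
        raise InvalidInputError(f"b must be finite, got {b!r}")
    return value_n * weight_kg**b


def normalize_record(
    record: MeasurementRecord, exponents: AllometricExponents
) -> NormalizedProfile:
    """Normalise every value present in ``record``; key set is preserved."""
    values = {}
    for param, value in record.values.items():
        try:
            b = exponents[param]
        except KeyError:
            raise ConfigurationError(
                f"no allometric exponent configured for {param.value}"
            ) from None
        values[param] = normalize_value(value, record.weight_kg, b)
    return NormalizedProfile(
        subject_id=record.subject_id,
        values=values,
        weight_warning=record.weight_kg > WEIGHT_VALIDATED_MAX_KG,
    )
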