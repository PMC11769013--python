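"""Assignment of normalised patient values to boxes 1-9.

Boxes are half-open ``[b_{k-1}, b_k)`` against the *continuous* boundaries,
with box 9 closed at the top, so every finite value maps to exactly one
box.  A value exactly at the healthy 1st percentile therefore lands in
box 4 (normal).  Values outside ``[b0, b9]`` are clamped to box 1 or 9 and
flagged rather than rejected — the grid is meant to absorb the full range
seen in practice without losing the fact that a value fell off it.
"""

from __future__ import annotations

import enum
import math
from bisect import bisect_right
from dataclasses import dataclass
from typing import Mapping

from .boxbuilder import BoxLimits
from .errors import ConfigurationError, InvalidInputError
from .normalization import NormalizedProfile
from .params import DISPLAY_ORDER, Parameter


class Zone(str, enum.Enum):
    BELOW_NORMAL = "BELOW_NORMAL"
    NORMAL = "NORMAL"
    ABOVE_NORMAL = "ABOVE_NORMAL"


class OutOfRange(str, enum.Enum):
    NONE = "NONE"
    BELOW_MIN = "BELOW_MIN"
    ABOVE_MAX = "ABOVE_MAX"


def zone_of_box(box: int) -> Zone:
    if box <= 3:
        return Zone.BELOW_NORMAL
    if box <= 6:
        return Zone.NORMAL
    return Zone.ABOVE_NORMAL


@dataclass(frozen=True)
class BoxAssignment:
    """One parameter's value placed in its box."""

    parameter: Parameter
    value: float
    box: int
    zone: Zone
    out_of_range: OutOfRange

    def __post_init__(self) -> None:
        if not 1 <= self.box <= 9:
            raise InvalidInputError(f"box must be 1..9, got {self.box}")
        if self.zone is not zone_of_box(self.box):
            raise InvalidInputError(f"zone {self.zone} inconsistent with box {self.box}")
        if self.out_of_range is OutOfRange.BELOW_MIN and self.box != 1:
            raise InvalidInputError("BELOW_MIN forces box 1")
        if self.out_of_range is OutOfRange.ABOVE_MAX and self.box != 9:
            raise InvalidInputError("ABOVE_MAX forces box 9")


@dataclass(frozen=True)
class CardioboxProfile:
    """A patient's full set of box assignments, ready to render."""

    subject_id: str
    assignments: tuple[BoxAssignment, ...]
    limits_provenance: str = ""

    def __post_init__(self) -> None:
        params = [a.parameter for a in self.assignments]
        if len(params) != len(set(params)):
            raise InvalidInputError("at most one assignment per parameter")

    def assignment(self, parameter: Parameter) -> BoxAssignment:
        for a in self.assignments:
            if a.parameter is parameter:
                return a
        raise KeyError(parameter)


def assign_box(value: float, limits: BoxLimits) -> BoxAssignment:
    """Place one value using the continuous boundaries of ``limits``."""
    if not math.isfinite(value):
        raise InvalidInputError(f"value must be finite, got {value!r}")
    b = limits.boundaries
    i = bisect_right(b, value)
    if i == 0:  # below the overall minimum
        box, oor = 1, OutOfRange.BELOW_MIN
    elif i >= 10:  # box 9 is closed at b9; beyond it is clamped + flagged
        box = 9
        oor = OutOfRange.ABOVE_MAX if value > b[9] else OutOfRange.NONE
    else:
        box, oor = i, OutOfRange.NONE
    return BoxAssignment(
        parameter=limits.parameter,
        value=value,
        box=box,
        zone=zone_of_box(box),
        out_of_range=oor,
    )


def classify_profile(
    profile: NormalizedProfile, limits_set: Mapping[Parameter, BoxLimits]
) -> CardioboxProfile:
    """Assign every parameter present in ``profile``, in display order."""
    missing = [p.value for p in profile.values if p not in limits_set]
    if missing:
        raise ConfigurationError(f"no box limits for parameter(s): {', '.join(missing)}")
    assignments = tuple(
        assign_box(profile.values[param], limits_set[param])
        for param in DISPLAY_ORDER
        if param in profile.values
    )
    strategies = {limits_set[a.parameter].strategy.value for a in assignments}
    provenance = ",".join(sorted(strategies))
    return CardioboxProfile(
        subject_id=profile.subject_id,
        assignments=assignments,
        limits_provenance=provenance,
    )
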