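"""Vocabulary shared across the package.

The grid covers the seven linear cardiac dimensions that scale with body
weight: the left atrial internal diameter in diastole (AID) plus the three
classic M-mode pairs measured in diastole and systole — interventricular
septal thickness (IVSd/IVSs), left ventricular internal diameter
(LVIDd/LVIDs) and left ventricular free-wall thickness (PLVWd/PLVWs).
"""

from __future__ import annotations

import enum


class Parameter(str, enum.Enum):
    """One of the seven echocardiographic dimensions (raw values in cm)."""

    AID = "AID"
    IVSD = "IVSD"
    LVIDD = "LVIDD"
    PLVWD = "PLVWD"
    IVSS = "IVSS"
    LVIDS = "LVIDS"
    PLVWS = "PLVWS"

    @property
    def normalized_name(self) -> str:
        """Label of the weight-normalised quantity (the 'n' suffix)."""
        return _NORMALIZED_NAMES[self]

    @classmethod
    def from_normalized_name(cls, name: str) -> "Parameter":
        try:
            return _FROM_NORMALIZED[name]
        except KeyError:
            raise ValueError(f"unknown normalised parameter name: {name!r}") from None

    @classmethod
    def from_any_name(cls, name: str) -> "Parameter":
        """Accept either the raw label (AID) or the normalised one (AIDn)."""
        if name in _FROM_NORMALIZED:
            return _FROM_NORMALIZED[name]
        return cls(name)


# The diastolic septum is conventionally labelled IVSSDn in normalised form.
_NORMALIZED_NAMES = {
    Parameter.AID: "AIDn",
    Parameter.IVSD: "IVSSDn",
    Parameter.LVIDD: "LVIDDn",
    Parameter.PLVWD: "PLVWDn",
    Parameter.IVSS: "IVSSn",
    Parameter.LVIDS: "LVIDSn",
    Parameter.PLVWS: "PLVWSn",
}
_FROM_NORMALIZED = {v: k for k, v in _NORMALIZED_NAMES.items()}

#: Canonical row order of the box chart and of all tabular output.
DISPLAY_ORDER: tuple[Parameter, ...] = (
    Parameter.AID,
    Parameter.IVSD,
    Parameter.LVIDD,
    Parameter.PLVWD,
    Parameter.IVSS,
    Parameter.LVIDS,
    Parameter.PLVWS,
)


class Group(str, enum.Enum):
    """Health status of a single animal."""

    HEALTHY = "HEALTHY"
    CARDIAC = "CARDIAC"


class Population(str, enum.Enum):
    """Reference population a percentile summary was computed over.

    TOTAL pools the healthy and cardiac groups; it supplies the outer
    bounds of the grid, while HEALTHY supplies the normal range.
    """

    HEALTHY = "HEALTHY"
    TOTAL = "TOTAL"
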