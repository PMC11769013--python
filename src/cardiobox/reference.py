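"""Percentile reference summaries over healthy and total populations.

Each parameter is summarised by eleven anchor percentiles
(min, 1, 2.5, 5, 25, 50, 75, 95, 97.5, 99, max) computed over the
weight-normalised values of a population.  Two populations matter:

* ``HEALTHY`` — animals with no cardiac or systemic disease; their 1st and
  99th percentiles bound the normal range of the grid.
* ``TOTAL`` — healthy plus cardiac animals pooled; their extremes and 99th
  percentile bound the outer boxes.

A transcription of the published reference grid (802 healthy / 2967 total
dogs under 20 kg) ships with the package; see :func:`load_packaged_reference`.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyDataError,
    InvalidDataError,
    InsufficientReferenceError,
    InvalidSummaryError,
)
from .normalization import AllometricExponents, MeasurementRecord, normalize_record
from .params import DISPLAY_ORDER, Group, Parameter, Population

#: Probabilities of the eleven anchor percentiles, in tabulated order.
ANCHOR_PROBS: tuple[float, ...] = (
    0.0, 0.01, 0.025, 0.05, 0.25, 0.50, 0.75, 0.95, 0.975, 0.99, 1.0,
)
#: Column labels used in CSV serialisation, aligned with ANCHOR_PROBS.
ANCHOR_LABELS: tuple[str, ...] = (
    "min", "p1", "p2.5", "p5", "p25", "p50", "p75", "p95", "p97.5", "p99", "max",
)

_DEFAULT_ESTIMATOR = "linear"  # interpolated order statistics (the "type 7" rule)


@dataclass(frozen=True)
class PercentileSummary:
    """Eleven anchor percentiles of one parameter in one population.

    ``anchors`` holds the values aligned with :data:`ANCHOR_PROBS`;
    ``estimator`` records the quantile convention used to compute them.
    """

    parameter: Parameter
    population: Population
    n: int
    anchors: tuple[float, ...]
    estimator: str = field(default=_DEFAULT_ESTIMATOR)

    def __post_init__(self) -> None:
        if len(self.anchors) != len(ANCHOR_PROBS):
            raise InvalidSummaryError(
                f"{self.parameter.value}/{self.population.value}: expected "
                f"{len(ANCHOR_PROBS)} anchors, got {len(self.anchors)}"
            )
        arr = np.asarray(self.anchors, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise InvalidSummaryError(
                f"{self.parameter.value}/{self.population.value}: non-finite anchor"
            )
        if np.any(np.diff(arr) < 0):
            raise InvalidSummaryError(
                f"{self.parameter.value}/{self.population.value}: anchors must be "
                "non-decreasing in probability"
            )
        if self.n <= 0:
            raise InvalidSummaryError(
                f"{self.parameter.value}/{self.population.value}: n must be positive"
            )

    def anchor(self, prob: float) -> float:
        """Value at one of the eleven anchor probabilities."""
        try:
            return self.anchors[ANCHOR_PROBS.index(prob)]
        except ValueError:
            raise KeyError(f"{prob} is not an anchor probability") from None

    @property
    def minimum(self) -> float:
        return self.anchors[0]

    @property
    def p1(self) -> float:
        return self.anchors[1]

    @property
    def median(self) -> float:
        return self.anchors[5]

    @property
    def p99(self) -> float:
        return self.anchors[9]

    @property
    def maximum(self) -> float:
        return self.anchors[10]

    def as_dict(self) -> dict[float, float]:
        return dict(zip(ANCHOR_PROBS, self.anchors))


class ReferenceTable:
    """All percentile summaries, keyed by (parameter, population)."""

    def __init__(self, summaries: Iterable[PercentileSummary] = ()) -> None:
        self._summaries: dict[tuple[Parameter, Population], PercentileSummary] = {}
        for s in summaries:
            self.add(s)

    def add(self, summary: PercentileSummary) -> None:
        self._summaries[(summary.parameter, summary.population)] = summary

    def summary(self, parameter: Parameter, population: Population) -> PercentileSummary:
        try:
            return self._summaries[(parameter, population)]
        except KeyError:
            raise KeyError(
                f"no {population.value} summary for {parameter.value}"
            ) from None

    def __contains__(self, key: tuple[Parameter, Population]) -> bool:
        return key in self._summaries

    def __len__(self) -> int:
        return len(self._summaries)

    @property
    def parameters(self) -> tuple[Parameter, ...]:
        """Parameters with both a HEALTHY and a TOTAL summary, display order."""
        return tuple(
            p
            for p in DISPLAY_ORDER
            if (p, Population.HEALTHY) in self._summaries
            and (p, Population.TOTAL) in self._summaries
        )

    def validate(self) -> None:
        """Check the pairing invariants (both populations, healthy n <= total n)."""
        for (param, pop), s in self._summaries.items():
            other = (
                Population.TOTAL if pop is Population.HEALTHY else Population.HEALTHY
            )
            if (param, other) not in self._summaries:
                raise InvalidSummaryError(
                    f"{param.value}: {pop.value} summary present but {other.value} missing"
                )
        for param in self.parameters:
            h = self.summary(param, Population.HEALTHY)
            t = self.summary(param, Population.TOTAL)
            if h.n > t.n:
                raise InvalidSummaryError(
                    f"{param.value}: healthy n ({h.n}) exceeds total n ({t.n})"
                )

    # ---- serialisation -------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pop in (Population.HEALTHY, Population.TOTAL):
            for param in DISPLAY_ORDER:
                if (param, pop) not in self._summaries:
                    continue
                s = self._summaries[(param, pop)]
                row: dict[str, object] = {
                    "parameter": param.normalized_name,
                    "population": pop.value,
                    "n": s.n,
                }
                row.update(dict(zip(ANCHOR_LABELS, s.anchors)))
                rows.append(row)
        return pd.DataFrame(rows, columns=["parameter", "population", "n", *ANCHOR_LABELS])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, estimator: str = _DEFAULT_ESTIMATOR) -> "ReferenceTable":
        required = {"parameter", "population", "n", *ANCHOR_LABELS}
        missing = required - set(frame.columns)
        if missing:
            raise InvalidDataError(f"reference table missing columns: {sorted(missing)}")
        table = cls()
        for _, row in frame.iterrows():
            table.add(
                PercentileSummary(
                    parameter=Parameter.from_any_name(str(row["parameter"])),
                    population=Population(str(row["population"])),
                    n=int(row["n"]),
                    anchors=tuple(float(row[label]) for label in ANCHOR_LABELS),
                    estimator=estimator,
                )
            )
        table.validate()
        return table

    @classmethod
    def from_csv(cls, path: str | Path) -> "ReferenceTable":
        try:
            frame = pd.read_csv(path, comment="#")
        except Exception as exc:  # surface parse errors with file context
            raise InvalidDataError(f"cannot parse reference CSV {path}: {exc}") from exc
        return cls.from_frame(frame)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "anchor_probs": list(ANCHOR_PROBS),
            "summaries": [
                {
                    "parameter": s.parameter.value,
                    "population": s.population.value,
                    "n": s.n,
                    "anchors": list(s.anchors),
                    "estimator": s.estimator,
                }
                for s in self._summaries.values()
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ReferenceTable":
        payload = json.loads(Path(path).read_text())
        table = cls(
            PercentileSummary(
                parameter=Parameter(d["parameter"]),
                population=Population(d["population"]),
                n=int(d["n"]),
                anchors=tuple(float(x) for x in d["anchors"]),
                estimator=d.get("estimator", _DEFAULT_ESTIMATOR),
            )
            for d in payload["summaries"]
        )
        table.validate()
        return table


def compute_percentile_summary(
    values: Sequence[float] | np.ndarray,
    parameter: Parameter,
    population: Population,
) -> PercentileSummary:
    """Summarise a sample at the eleven anchor probabilities.

    Quantiles are interpolated order statistics (numpy's ``linear`` method,
    the "type 7" convention); the extremes are the sample min and max.
    The convention is recorded on the summary so alternative estimators can
    be compared downstream.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise EmptyDataError(f"no values to summarise for {parameter.value}")
    if not np.all(np.isfinite(arr)):
        raise InvalidDataError(f"non-finite value in {parameter.value} sample")
    anchors = np.quantile(arr, ANCHOR_PROBS, method="linear")
    return PercentileSummary(
        parameter=parameter,
        population=population,
        n=int(arr.size),
        anchors=tuple(float(a) for a in anchors),
    )


def build_reference_table(
    records: Sequence[MeasurementRecord], exponents: AllometricExponents
) -> ReferenceTable:
    """Normalise all records and summarise each parameter per population.

    HEALTHY summaries use healthy records only; TOTAL summaries pool all
    records.  Per-parameter n counts only records where that parameter was
    measured (missing values are skipped, never imputed).
    """
    if not any(r.group is Group.HEALTHY for r in records):
        raise InsufficientReferenceError("reference requires at least one healthy record")
    healthy_values: dict[Parameter, list[float]] = {p: [] for p in Parameter}
    total_values: dict[Parameter, list[float]] = {p: [] for p in Parameter}
    for record in records:
        profile = normalize_record(record, exponents)
        for param, value in profile.values.items():
            total_values[param].append(value)
            if record.group is Group.HEALTHY:
                healthy_values[param].append(value)
    table = ReferenceTable()
    for param in Parameter:
        if not healthy_values[param]:
            continue
        table.add(compute_percentile_summary(healthy_values[param], param, Population.HEALTHY))
        table.add(compute_percentile_summary(total_values[param], param, Population.TOTAL))
    table.validate()
    return table


def load_packaged_reference() -> ReferenceTable:
    """The packaged reference grid (802 healthy / 2967 total dogs < 20 kg)."""
    resource = importlib.resources.files("cardiobox.data").joinpath("reference_percentiles.csv")
    with importlib.resources.as_file(resource) as path:
        table = ReferenceTable.from_csv(path)
    # Published values: the estimator behind them is not recorded anywhere.
    return ReferenceTable(
        PercentileSummary(s.parameter, s.population, s.n, s.anchors, estimator="as-published")
        for s in table._summaries.values()
    )
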