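"""Construction of the 9-box limits per parameter.

The grid partitions ``[total.min, total.max]`` into nine contiguous boxes:

* boxes 1-3 (below normal) split ``[total.min, healthy.P1]`` into three
  equal-width intervals;
* boxes 4-6 (normal, drawn grey) split ``[healthy.P1, healthy.P99]`` into
  three equal-width intervals;
* boxes 7-9 (above normal) cover ``[healthy.P99, total.max]``.

Two rules for the upper region are supported, because the published grid
and its own verbal description disagree there:

* ``TABLE_CONSISTENT`` (default): the box-8/9 boundary is the TOTAL
  population's 99th percentile and the box-7/8 boundary is the midpoint of
  the healthy and total 99th percentiles.  This is the rule the published
  limits actually follow, for every parameter.
* ``PROSE_EQUAL_THIRDS``: three equal-width boxes between healthy P99 and
  the total maximum — the literal reading of the published description,
  which reproduces none of the published upper-region limits.

Internal arithmetic is continuous; the 2-decimal displayed pairs are
presentation only (classification always uses the continuous boundaries).
"""

from __future__ import annotations

import enum
import importlib.resources
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import InconsistentReferenceError, InvalidDataError, InvalidInputError
from .params import DISPLAY_ORDER, Parameter, Population
from .reference import PercentileSummary, ReferenceTable


class Strategy(str, enum.Enum):
    """Rule used for the boundaries of boxes 7-9."""

    TABLE_CONSISTENT = "TABLE_CONSISTENT"
    PROSE_EQUAL_THIRDS = "PROSE_EQUAL_THIRDS"


@dataclass(frozen=True)
class BoxLimits:
    """Continuous boundaries b0..b9 and displayed 2-decimal pairs for one parameter.

    ``median_offset`` is a diagnostic: the healthy median minus the centre
    of box 5.  The equal-thirds normal region does not in general centre
    box 5 on the median; the offset is reported rather than enforced.
    """

    parameter: Parameter
    boundaries: tuple[float, ...]
    displayed: tuple[tuple[float, float], ...]
    strategy: Strategy
    precision: float = 0.01
    provenance: Mapping[str, float] = field(default_factory=dict)
    median_offset: float = float("nan")

    def __post_init__(self) -> None:
        if len(self.boundaries) != 10:
            raise InvalidInputError(
                f"{self.parameter.value}: expected 10 boundaries, got {len(self.boundaries)}"
            )
        if any(b1 >= b2 for b1, b2 in zip(self.boundaries, self.boundaries[1:])):
            raise InconsistentReferenceError(
                f"{self.parameter.value}: boundaries must be strictly increasing"
            )
        if len(self.displayed) != 9:
            raise InvalidInputError(
                f"{self.parameter.value}: expected 9 displayed pairs, got {len(self.displayed)}"
            )


def _grid(units: int, precision: float) -> float:
    return round(units * precision, 10)


def display_bounds(
    boundaries: Sequence[float], precision: float = 0.01
) -> tuple[tuple[float, float], ...]:
    """Render ten continuous boundaries as nine inclusive (lower, upper) pairs.

    The pairs live on a grid of step ``precision`` with a one-step gap
    between adjacent boxes.  An interior boundary belongs to the box above
    it (consistent with half-open classification): the upper box's lower
    bound is the boundary rounded up to the grid, and the lower box's upper
    bound is one step below that.  The four anchor boundaries (overall min,
    healthy P1, healthy P99, overall max) round to nearest instead, so the
    printed normal range starts exactly at P1 and ends exactly at P99.
    """
    b = [float(x) for x in boundaries]
    if len(b) != 10:
        raise InvalidInputError(f"expected 10 boundaries, got {len(b)}")
    if any(x >= y for x, y in zip(b, b[1:])):
        raise InvalidInputError("boundaries must be strictly increasing")
    if not (precision > 0):
        raise InvalidInputError(f"precision must be positive, got {precision!r}")

    # Work in grid units; round at 1e-4 grid units to absorb float noise
    # from the thirds/midpoint arithmetic without moving real boundaries.
    gu = [round(x / precision, 4) for x in b]
    lowers: list[float] = [0.0] * 9
    uppers: list[float] = [0.0] * 9
    lowers[0] = _grid(round(gu[0]), precision)
    uppers[8] = _grid(round(gu[9]), precision)
    for k in (1, 2, 4, 5, 7, 8):  # interior, non-anchor boundaries
        lo_units = math.ceil(gu[k])
        uppers[k - 1] = _grid(lo_units - 1, precision)
        lowers[k] = _grid(lo_units, precision)
    # anchors: healthy P1 opens box 4, healthy P99 closes box 6
    p1_units = round(gu[3])
    uppers[2] = _grid(p1_units - 1, precision)
    lowers[3] = _grid(p1_units, precision)
    p99_units = round(gu[6])
    uppers[5] = _grid(p99_units, precision)
    lowers[6] = _grid(p99_units + 1, precision)

    pairs = tuple((lowers[i], uppers[i]) for i in range(9))
    for i, (lo, hi) in enumerate(pairs):
        if lo > hi:
            raise InvalidInputError(
                f"box {i + 1} collapses at precision {precision} (lower {lo} > upper {hi})"
            )
    return pairs


def build_box_limits(
    healthy: PercentileSummary,
    total: PercentileSummary,
    strategy: Strategy = Strategy.TABLE_CONSISTENT,
    precision: float = 0.01,
) -> BoxLimits:
    """Build the nine box limits for one parameter from its two summaries."""
    if healthy.parameter is not total.parameter:
        raise InvalidInputError(
            f"parameter mismatch: {healthy.parameter.value} vs {total.parameter.value}"
        )
    param = healthy.parameter
    t_min, t_max = total.minimum, total.maximum
    h_p1, h_p99 = healthy.p1, healthy.p99
    t_p99 = total.p99

    if not (t_min < h_p1):
        raise InconsistentReferenceError(
            f"{param.value}: lower region degenerate (total min {t_min} !< healthy P1 {h_p1})"
        )
    if not (h_p1 < h_p99):
        raise InconsistentReferenceError(
            f"{param.value}: normal range degenerate (healthy P1 {h_p1} !< P99 {h_p99})"
        )
    if not (h_p99 < t_max):
        raise InconsistentReferenceError(
            f"{param.value}: upper region degenerate (healthy P99 {h_p99} !< total max {t_max})"
        )

    w_low = (h_p1 - t_min) / 3.0
    w_norm = (h_p99 - h_p1) / 3.0
    if strategy is Strategy.TABLE_CONSISTENT:
        if not (h_p99 < t_p99 < t_max):
            raise InconsistentReferenceError(
                f"{param.value}: total P99 {t_p99} must lie strictly between healthy "
                f"P99 {h_p99} and total max {t_max} under TABLE_CONSISTENT"
            )
        b7 = (h_p99 + t_p99) / 2.0
        b8 = t_p99
    else:
        w_up = (t_max - h_p99) / 3.0
        b7 = h_p99 + w_up
        b8 = h_p99 + 2.0 * w_up

    boundaries = (
        t_min,
        t_min + w_low,
        t_min + 2.0 * w_low,
        h_p1,
        h_p1 + w_norm,
        h_p1 + 2.0 * w_norm,
        h_p99,
        b7,
        b8,
        t_max,
    )
    return BoxLimits(
        parameter=param,
        boundaries=boundaries,
        displayed=display_bounds(boundaries, precision),
        strategy=strategy,
        precision=precision,
        provenance={
            "healthy_n": healthy.n,
            "total_n": total.n,
            "healthy_p1": h_p1,
            "healthy_p99": h_p99,
            "total_min": t_min,
            "total_p99": t_p99,
            "total_max": t_max,
        },
        median_offset=healthy.median - (boundaries[4] + boundaries[5]) / 2.0,
    )


def build_all(
    reference: ReferenceTable,
    strategy: Strategy = Strategy.TABLE_CONSISTENT,
    precision: float = 0.01,
) -> dict[Parameter, BoxLimits]:
    """Box limits for every parameter with both summaries, display order."""
    limits: dict[Parameter, BoxLimits] = {}
    for param in reference.parameters:
        limits[param] = build_box_limits(
            reference.summary(param, Population.HEALTHY),
            reference.summary(param, Population.TOTAL),
            strategy=strategy,
            precision=precision,
        )
    return limits


# ---- serialisation ------------------------------------------------------


def limits_to_frame(limits: Mapping[Parameter, BoxLimits]) -> pd.DataFrame:
    """Displayed pairs as a table (parameter row, 18 bound columns)."""
    columns = ["parameter"]
    for k in range(1, 10):
        columns += [f"box{k}_lower", f"box{k}_upper"]
    rows = []
    for param in DISPLAY_ORDER:
        if param not in limits:
            continue
        row: dict[str, object] = {"parameter": param.normalized_name}
        for k, (lo, hi) in enumerate(limits[param].displayed, start=1):
            row[f"box{k}_lower"] = lo
            row[f"box{k}_upper"] = hi
        rows.append(row)
    return pd.DataFrame(rows, columns=columns)


def limits_to_csv(limits: Mapping[Parameter, BoxLimits], path: str | Path) -> None:
    limits_to_frame(limits).to_csv(path, index=False, float_format="%.2f")


def limits_to_json(limits: Mapping[Parameter, BoxLimits], path: str | Path) -> None:
    payload = [
        {
            "parameter": lim.parameter.value,
            "strategy": lim.strategy.value,
            "precision": lim.precision,
            "boundaries": list(lim.boundaries),
            "displayed": [list(pair) for pair in lim.displayed],
            "provenance": dict(lim.provenance),
            "median_offset": lim.median_offset,
        }
        for param in DISPLAY_ORDER
        if (lim := limits.get(param)) is not None
    ]
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def limits_from_json(path: str | Path) -> dict[Parameter, BoxLimits]:
    payload = json.loads(Path(path).read_text())
    limits: dict[Parameter, BoxLimits] = {}
    for d in payload:
        param = Parameter(d["parameter"])
        limits[param] = BoxLimits(
            parameter=param,
            boundaries=tuple(float(x) for x in d["boundaries"]),
            displayed=tuple((float(lo), float(hi)) for lo, hi in d["displayed"]),
            strategy=Strategy(d["strategy"]),
            precision=float(d["precision"]),
            provenance=d.get("provenance", {}),
            median_offset=float(d.get("median_offset", "nan")),
        )
    return limits


def displayed_from_csv(path: str | Path) -> dict[Parameter, tuple[tuple[float, float], ...]]:
    """Read a displayed-pairs CSV (the layout written by limits_to_csv)."""
    try:
        frame = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise InvalidDataError(f"cannot parse box-limit CSV {path}: {exc}") from exc
    out: dict[Parameter, tuple[tuple[float, float], ...]] = {}
    for _, row in frame.iterrows():
        param = Parameter.from_any_name(str(row["parameter"]))
        out[param] = tuple(
            (float(row[f"box{k}_lower"]), float(row[f"box{k}_upper"])) for k in range(1, 10)
        )
    return out


def load_packaged_displayed_limits() -> dict[Parameter, tuple[tuple[float, float], ...]]:
    """The packaged published displayed limits (presentation-layer reference)."""
    resource = importlib.resources.files("cardiobox.data").joinpath("published_box_limits.csv")
    with importlib.resources.as_file(resource) as path:
        return displayed_from_csv(path)
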