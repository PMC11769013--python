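"""File round-trips: measurement/patient CSVs, assignment tables, atomic writes.

CSV dialect everywhere: comma separators, dot decimals, UTF-8, mandatory
header row; lines starting with ``#`` are comments.
"""

from __future__ import annotations

import os
import tempfile
from contextlib import contextmanager
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import pandas as pd

from .classify import BoxAssignment, CardioboxProfile, OutOfRange, Zone
from .errors import InvalidDataError
from .normalization import MeasurementRecord, NormalizedProfile
from .params import DISPLAY_ORDER, Group, Parameter


@contextmanager
def atomic_write(path: str | Path) -> Iterator:
    """Write to a temp file and rename on success; no partial outputs."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp_name = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", text=True)
    tmp = Path(tmp_name)
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="") as handle:
            yield handle
        os.replace(tmp, path)
    except BaseException:
        tmp.unlink(missing_ok=True)
        raise


# ---- measurement populations -------------------------------------------


def write_measurements(
    records: Sequence[MeasurementRecord], path: str | Path, comment: str | None = None
) -> None:
    """Write one row per animal: subject_id, group, weight_kg, raw cm columns."""
    columns = ["subject_id", "group", "weight_kg"] + [p.value for p in DISPLAY_ORDER]
    with atomic_write(path) as handle:
        if comment:
            handle.write(f"# {comment}\n")
        handle.write(",".join(columns) + "\n")
        for r in records:
            cells = [r.subject_id, r.group.value, repr(float(r.weight_kg))]
            for p in DISPLAY_ORDER:
                cells.append(repr(float(r.values[p])) if p in r.values else "")
            handle.write(",".join(cells) + "\n")


def read_measurements(path: str | Path) -> list[MeasurementRecord]:
    try:
        frame = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise InvalidDataError(f"cannot parse measurement CSV {path}: {exc}") from exc
    required = {"subject_id", "group", "weight_kg"}
    if missing := required - set(frame.columns):
        raise InvalidDataError(f"measurement CSV missing columns: {sorted(missing)}")
    param_cols = [p for p in DISPLAY_ORDER if p.value in frame.columns]
    records = []
    for _, row in frame.iterrows():
        values = {
            p: float(row[p.value]) for p in param_cols if pd.notna(row[p.value])
        }
        records.append(
            MeasurementRecord(
                subject_id=str(row["subject_id"]),
                weight_kg=float(row["weight_kg"]),
                group=Group(str(row["group"])),
                values=values,
            )
        )
    return records


# ---- patient tables -----------------------------------------------------


def read_patients(
    path: str | Path,
) -> list[tuple[str, float | None, dict[Parameter, float], dict[Parameter, float]]]:
    """Read a patient CSV.

    Returns ``(subject_id, weight_kg or None, raw_values, normalized_values)``
    per row.  Raw columns use the plain parameter names (cm); pre-normalised
    columns use the 'n'-suffixed names.
    """
    try:
        frame = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise InvalidDataError(f"cannot parse patient CSV {path}: {exc}") from exc
    if "subject_id" not in frame.columns:
        raise InvalidDataError(f"patient CSV {path} lacks a subject_id column")
    raw_cols = [p for p in DISPLAY_ORDER if p.value in frame.columns]
    norm_cols = [p for p in DISPLAY_ORDER if p.normalized_name in frame.columns]
    patients = []
    for _, row in frame.iterrows():
        weight = float(row["weight_kg"]) if "weight_kg" in frame.columns and pd.notna(row.get("weight_kg")) else None
        raw = {p: float(row[p.value]) for p in raw_cols if pd.notna(row[p.value])}
        norm = {p: float(row[p.normalized_name]) for p in norm_cols if pd.notna(row[p.normalized_name])}
        patients.append((str(row["subject_id"]), weight, raw, norm))
    return patients


# ---- assignments --------------------------------------------------------

_ASSIGNMENT_COLUMNS = ["subject_id", "parameter", "value", "box", "zone", "out_of_range"]


def write_assignments(profiles: Sequence[CardioboxProfile], path: str | Path) -> None:
    with atomic_write(path) as handle:
        handle.write(",".join(_ASSIGNMENT_COLUMNS) + "\n")
        for profile in profiles:
            for a in profile.assignments:
                handle.write(
                    f"{profile.subject_id},{a.parameter.normalized_name},"
                    f"{repr(float(a.value))},{a.box},{a.zone.value},{a.out_of_range.value}\n"
                )


def read_assignments(path: str | Path) -> dict[str, CardioboxProfile]:
    try:
        frame = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise InvalidDataError(f"cannot parse assignments CSV {path}: {exc}") from exc
    if missing := set(_ASSIGNMENT_COLUMNS) - set(frame.columns):
        raise InvalidDataError(f"assignments CSV missing columns: {sorted(missing)}")
    by_subject: dict[str, list[BoxAssignment]] = {}
    for _, row in frame.iterrows():
        assignment = BoxAssignment(
            parameter=Parameter.from_any_name(str(row["parameter"])),
            value=float(row["value"]),
            box=int(row["box"]),
            zone=Zone(str(row["zone"])),
            out_of_range=OutOfRange(str(row["out_of_range"])),
        )
        by_subject.setdefault(str(row["subject_id"]), []).append(assignment)
    return {
        subject: CardioboxProfile(subject, tuple(assignments))
        for subject, assignments in by_subject.items()
    }
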