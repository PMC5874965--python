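"""Reading, validating and writing couch-offset QA logs and offset-experiment tables.

The on-disk format is a plain comma-separated, UTF-8 file with header

    timestamp,unit_id,axis,offset_mm,energy_pct,output_pct,gantry_phase_deg

for measurement logs, and

    axis,applied_mm,detected_x_mm,detected_y_mm,detected_z_mm,energy_pct,output_pct,gantry_phase_deg,replicate

for applied-vs-detected offset experiments.  Optional columns may be left
empty.  Offsets are serialized with enough decimals that a write/read
round-trip preserves every field.

Timestamps are ISO-8601; naive (zone-less) stamps are accepted and ordered
lexically, which for ISO strings coincides with chronological order.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable, Sequence

import numpy as np

from .errors import EmptySelectionError, QAParseError

AXES = ("IECX", "IECY", "IECZ")

#: hard sanity bound on |offset| — a couch offset beyond this is a corrupt row
MAX_ABS_OFFSET_MM = 50.0

LOG_COLUMNS = (
    "timestamp",
    "unit_id",
    "axis",
    "offset_mm",
    "energy_pct",
    "output_pct",
    "gantry_phase_deg",
)

EXPERIMENT_COLUMNS = (
    "axis",
    "applied_mm",
    "detected_x_mm",
    "detected_y_mm",
    "detected_z_mm",
    "energy_pct",
    "output_pct",
    "gantry_phase_deg",
    "replicate",
)


@dataclass(frozen=True)
class QARecord:
    """One couch-offset QA measurement for one machine axis."""

    timestamp: str
    unit_id: str
    axis: str
    offset_mm: float
    energy_pct: float | None = None
    output_pct: float | None = None
    gantry_phase_deg: float | None = None

    def validate(self) -> None:
        if self.axis not in AXES:
            raise ValueError(f"axis must be one of {AXES}, got {self.axis!r}")
        if not np.isfinite(self.offset_mm) or abs(self.offset_mm) >= MAX_ABS_OFFSET_MM:
            raise ValueError(
                f"offset_mm must be finite and |offset| < {MAX_ABS_OFFSET_MM}, "
                f"got {self.offset_mm!r}"
            )
        # raises ValueError on malformed stamps
        datetime.fromisoformat(self.timestamp)


@dataclass
class QASeries:
    """Ordered offset measurements x_1..x_n for one (unit, axis).

    This is the container every chart/normality/capability routine consumes.
    ``values`` and ``timestamps`` are parallel and time-ordered.
    """

    unit_id: str
    axis: str
    values: np.ndarray
    timestamps: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("values must be a non-empty 1-D array")
        if self.timestamps and len(self.timestamps) != self.values.size:
            raise ValueError("timestamps and values must have equal length")
        if self.timestamps and any(
            a > b for a, b in zip(self.timestamps, self.timestamps[1:])
        ):
            raise ValueError("timestamps must be non-decreasing")

    @property
    def n(self) -> int:
        return int(self.values.size)

    def slice(self, start: int, end: int) -> "QASeries":
        """Half-open positional slice [start, end) preserving metadata."""
        return QASeries(
            unit_id=self.unit_id,
            axis=self.axis,
            values=self.values[start:end].copy(),
            timestamps=list(self.timestamps[start:end]) if self.timestamps else [],
        )


@dataclass(frozen=True)
class OffsetTrial:
    """One applied-offset experiment run: a shift applied on one axis and the
    offsets the detector reported on all three axes."""

    axis: str
    applied_mm: float
    detected_mm: tuple[float, float, float]  # (IECX, IECY, IECZ)
    energy_pct: float | None = None
    output_pct: float | None = None
    gantry_phase_deg: float | None = None
    replicate: int = 1

    def validate(self) -> None:
        if self.axis not in AXES:
            raise ValueError(f"axis must be one of {AXES}, got {self.axis!r}")
        if abs(self.applied_mm) > 10:
            raise ValueError(f"|applied_mm| must be <= 10, got {self.applied_mm}")
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")

    def detected_on(self, axis: str) -> float:
        return self.detected_mm[AXES.index(axis)]


# ---------------------------------------------------------------------------
# parsing helpers


def _opt_float(text: str, what: str) -> float | None:
    text = text.strip()
    if text == "":
        return None
    return float(text)


def _fmt_opt(value: float | None) -> str:
    return "" if value is None else repr(float(value))


def _check_header(header: Sequence[str], expected: Sequence[str], path) -> None:
    got = [h.strip() for h in header]
    if got != list(expected):
        missing = [c for c in expected if c not in got]
        if missing:
            raise QAParseError(
                f"{path}: missing/renamed mandatory column(s): {', '.join(missing)}"
            )
        raise QAParseError(
            f"{path}: header column order must be {','.join(expected)}, got {','.join(got)}"
        )


def read_qa_log(
    path,
    unit_filter: str | None = None,
    axis_filter: str | None = None,
    strict: bool = False,
    drop_invalid: bool = False,
):
    """Read a QA measurement log.

    Parameters
    ----------
    path : path-like
        CSV file in the package dialect (see module docstring).
    unit_filter, axis_filter : optional
        Keep only records for this unit / axis.
    strict : bool
        Abort on the first invalid row instead of scanning the whole file.
    drop_invalid : bool
        Return ``(records, row_errors)`` instead of raising when rows fail
        validation; invalid rows are reported, never silently dropped.

    Returns
    -------
    list of QARecord, in file order — or ``(records, row_errors)`` when
    ``drop_invalid`` is set.
    """
    records: list[QARecord] = []
    row_errors: list[tuple[int, str]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise QAParseError(f"{path}: empty file, expected header row")
        _check_header(header, LOG_COLUMNS, path)
        for lineno, row in enumerate(reader, start=2):
            if not row or all(cell.strip() == "" for cell in row):
                continue
            try:
                if len(row) != len(LOG_COLUMNS):
                    raise ValueError(
                        f"expected {len(LOG_COLUMNS)} fields, got {len(row)}"
                    )
                rec = QARecord(
                    timestamp=row[0].strip(),
                    unit_id=row[1].strip(),
                    axis=row[2].strip(),
                    offset_mm=float(row[3]),
                    energy_pct=_opt_float(row[4], "energy_pct"),
                    output_pct=_opt_float(row[5], "output_pct"),
                    gantry_phase_deg=_opt_float(row[6], "gantry_phase_deg"),
                )
                rec.validate()
            except ValueError as exc:
                msg = f"line {lineno}: {exc}"
                if strict:
                    raise QAParseError(f"{path}: {msg}", [(lineno, str(exc))])
                row_errors.append((lineno, str(exc)))
                continue
            if unit_filter is not None and rec.unit_id != unit_filter:
                continue
            if axis_filter is not None and rec.axis != axis_filter:
                continue
            records.append(rec)
    if row_errors and not drop_invalid:
        detail = "; ".join(f"line {ln}: {m}" for ln, m in row_errors)
        raise QAParseError(f"{path}: {len(row_errors)} invalid row(s): {detail}", row_errors)
    if drop_invalid:
        return records, row_errors
    return records


def write_qa_log(records: Iterable[QARecord], path) -> None:
    """Write records in the package CSV dialect; inverse of :func:`read_qa_log`."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(LOG_COLUMNS)
        for rec in records:
            rec.validate()
            writer.writerow(
                [
                    rec.timestamp,
                    rec.unit_id,
                    rec.axis,
                    repr(float(rec.offset_mm)),
                    _fmt_opt(rec.energy_pct),
                    _fmt_opt(rec.output_pct),
                    _fmt_opt(rec.gantry_phase_deg),
                ]
            )


def to_series(records: Sequence[QARecord], unit_id: str, axis: str) -> QASeries:
    """Extract the time-ordered offset series for one (unit, axis).

    Sorting is stable: ties in timestamp keep input order.
    """
    selected = [r for r in records if r.unit_id == unit_id and r.axis == axis]
    if not selected:
        raise EmptySelectionError(f"no records for unit={unit_id!r} axis={axis!r}")
    selected.sort(key=lambda r: r.timestamp)  # lexical ISO == chronological
    return QASeries(
        unit_id=unit_id,
        axis=axis,
        values=np.array([r.offset_mm for r in selected], dtype=float),
        timestamps=[r.timestamp for r in selected],
    )


def read_experiment(path, strict: bool = False) -> list[OffsetTrial]:
    """Read an applied-vs-detected offset experiment table."""
    trials: list[OffsetTrial] = []
    row_errors: list[tuple[int, str]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise QAParseError(f"{path}: empty file, expected header row")
        _check_header(header, EXPERIMENT_COLUMNS, path)
        for lineno, row in enumerate(reader, start=2):
            if not row or all(cell.strip() == "" for cell in row):
                continue
            try:
                if len(row) != len(EXPERIMENT_COLUMNS):
                    raise ValueError(
                        f"expected {len(EXPERIMENT_COLUMNS)} fields, got {len(row)}"
                    )
                trial = OffsetTrial(
                    axis=row[0].strip(),
                    applied_mm=float(row[1]),
                    detected_mm=(float(row[2]), float(row[3]), float(row[4])),
                    energy_pct=_opt_float(row[5], "energy_pct"),
                    output_pct=_opt_float(row[6], "output_pct"),
                    gantry_phase_deg=_opt_float(row[7], "gantry_phase_deg"),
                    replicate=int(row[8]),
                )
                trial.validate()
            except ValueError as exc:
                msg = (lineno, str(exc))
                if strict:
                    raise QAParseError(f"{path}: line {lineno}: {exc}", [msg])
                row_errors.append(msg)
                continue
            trials.append(trial)
    if row_errors:
        detail = "; ".join(f"line {ln}: {m}" for ln, m in row_errors)
        raise QAParseError(f"{path}: {len(row_errors)} invalid row(s): {detail}", row_errors)
    return trials


def write_experiment(trials: Iterable[OffsetTrial], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(EXPERIMENT_COLUMNS)
        for t in trials:
            t.validate()
            writer.writerow(
                [
                    t.axis,
                    repr(float(t.applied_mm)),
                    repr(float(t.detected_mm[0])),
                    repr(float(t.detected_mm[1])),
                    repr(float(t.detected_mm[2])),
                    _fmt_opt(t.energy_pct),
                    _fmt_opt(t.output_pct),
                    _fmt_opt(t.gantry_phase_deg),
                    str(int(t.replicate)),
                ]
            )
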