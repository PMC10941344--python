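"""Domain containers and plain-text I/O for RR-interval (tachogram) data.

The canonical unit throughout the package is the millisecond: RR intervals
are stored as positive floats (interpolated beats need not be integral),
and beat onset times are derived in seconds with the first beat at t = 0.

Text interchange formats
------------------------
Tachogram: either one interval per line (``#`` starts a comment line) or a
delimited variant with a ``rr_ms[,label]`` header.  Metrics tables are
comma-delimited UTF-8 with ``.`` as the decimal separator; floats are
written with ``repr`` so a read-back reproduces every value exactly.
"""
from __future__ import annotations

import csv
import os
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import EmptyInputError, ParseError, SchemaError

# Beat labels
NORMAL = "normal"
TECHNICAL_ARTIFACT = "technical_artifact"
ECTOPIC = "ectopic"
INTERPOLATED = "interpolated"
BEAT_LABELS = (NORMAL, TECHNICAL_ARTIFACT, ECTOPIC, INTERPOLATED)

# Recording conditions
REST = "rest"
SNSA_STIM = "snsa_stim"
RECOVERY = "recovery"
UNSPECIFIED = "unspecified"
CONDITIONS = (REST, SNSA_STIM, RECOVERY)


@dataclass(frozen=True)
class RRISeries:
    """A beat-to-beat RR-interval series in milliseconds.

    Parameters
    ----------
    values
        RR intervals in ms, all strictly positive.
    labels
        Per-beat annotation, one of :data:`BEAT_LABELS`; defaults to
        ``normal`` for every beat.
    subject_id
        Opaque identifier, kept for bookkeeping.
    condition
        One of ``rest``, ``snsa_stim``, ``recovery`` or ``unspecified``.
    """

    values: np.ndarray
    labels: np.ndarray = None  # type: ignore[assignment]
    subject_id: str = ""
    condition: str = UNSPECIFIED

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise ValueError("RR values must be one-dimensional")
        if values.size and not np.all(values > 0):
            raise ValueError("all RR intervals must be positive")
        object.__setattr__(self, "values", values)
        if self.labels is None:
            labels = np.full(values.size, NORMAL, dtype=object)
        else:
            labels = np.asarray(self.labels, dtype=object)
        if labels.shape != values.shape:
            raise ValueError("labels must have the same length as values")
        unknown = set(labels.tolist()) - set(BEAT_LABELS)
        if unknown:
            raise ValueError(f"unknown beat labels: {sorted(unknown)}")
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def onset_times(self) -> np.ndarray:
        """Cumulative beat onset times in seconds, first beat at 0."""
        out = np.empty(self.values.size)
        if out.size:
            out[0] = 0.0
            np.cumsum(self.values[:-1] / 1000.0, out=out[1:])
        return out

    @property
    def duration_s(self) -> float:
        """Total span covered by the beats, in seconds."""
        return float(self.values.sum() / 1000.0)

    def with_values(self, values: np.ndarray, labels: np.ndarray | None = None) -> "RRISeries":
        return RRISeries(
            values=values,
            labels=self.labels.copy() if labels is None else labels,
            subject_id=self.subject_id,
            condition=self.condition,
        )


@dataclass(frozen=True)
class ConditionRecording:
    """One recording of one subject under one condition."""

    series: RRISeries
    resp_rate: float | None = None  # breaths/min, from external counting
    duration_s: float | None = None  # nominal recording length

    def __post_init__(self) -> None:
        if self.resp_rate is not None and not (0 < self.resp_rate < 60):
            raise ValueError("resp_rate must lie in (0, 60) breaths/min")
        if self.duration_s is None:
            object.__setattr__(self, "duration_s", self.series.duration_s)
        elif self.duration_s <= 0:
            raise ValueError("duration_s must be positive")


@dataclass(frozen=True)
class SubjectRecord:
    """The unit of cohort analysis: all three condition recordings."""

    subject_id: str
    rest: ConditionRecording
    snsa_stim: ConditionRecording
    recovery: ConditionRecording
    career_duration: float | None = None  # years

    def recording(self, condition: str) -> ConditionRecording:
        if condition not in CONDITIONS:
            raise KeyError(condition)
        return getattr(self, condition)


def _open_maybe(source, mode: str = "r"):
    if hasattr(source, "read") or hasattr(source, "write"):
        return source, False
    return open(os.fspath(source), mode, encoding="utf-8", newline=""), True


def read_tachogram(
    source,
    dialect: str = "auto",
    unit: str = "ms",
    subject_id: str = "",
    condition: str = UNSPECIFIED,
) -> RRISeries:
    """Read a tachogram from a path or text stream.

    ``dialect`` is ``one-per-line``, ``delimited`` (``rr_ms[,label]``
    header) or ``auto`` to sniff from the first data line.  ``unit`` is
    ``ms`` or ``s``; seconds are converted to milliseconds.
    """
    if unit not in ("ms", "s"):
        raise ValueError("unit must be 'ms' or 's'")
    stream, close = _open_maybe(source)
    try:
        raw = stream.read()
    finally:
        if close:
            stream.close()
    if isinstance(raw, bytes):
        raw = raw.decode("utf-8")

    lines = raw.splitlines()
    data: list[tuple[int, str]] = []  # (1-based line number, text)
    for i, line in enumerate(lines, start=1):
        text = line.strip()
        if not text or text.startswith("#"):
            continue
        data.append((i, text))
    if not data:
        raise EmptyInputError("no numeric records in input")

    if dialect == "auto":
        first = data[0][1]
        dialect = "delimited" if ("," in first or first.split(",")[0].strip().lower() == "rr_ms") else "one-per-line"

    scale = 1000.0 if unit == "s" else 1.0
    values: list[float] = []
    labels: list[str] = []
    if dialect == "one-per-line":
        for lineno, text in data:
            try:
                values.append(float(text) * scale)
            except ValueError:
                raise ParseError(f"line {lineno}: could not parse {text!r} as a number") from None
            labels.append(NORMAL)
    elif dialect == "delimited":
        header_no, header = data[0]
        cols = [c.strip().lower() for c in header.split(",")]
        if cols[0] != "rr_ms":
            raise ParseError(f"line {header_no}: expected header starting with 'rr_ms', got {header!r}")
        has_label = len(cols) > 1 and cols[1] == "label"
        for lineno, text in data[1:]:
            parts = [p.strip() for p in text.split(",")]
            try:
                values.append(float(parts[0]) * scale)
            except ValueError:
                raise ParseError(f"line {lineno}: could not parse {parts[0]!r} as a number") from None
            if has_label and len(parts) > 1 and parts[1]:
                if parts[1] not in BEAT_LABELS:
                    raise ParseError(f"line {lineno}: unknown beat label {parts[1]!r}")
                labels.append(parts[1])
            else:
                labels.append(NORMAL)
        if not values:
            raise EmptyInputError("no numeric records after header")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    return RRISeries(
        values=np.asarray(values),
        labels=np.asarray(labels, dtype=object),
        subject_id=subject_id,
        condition=condition,
    )


def write_tachogram(series: RRISeries, destination, include_labels: bool | None = None) -> None:
    """Write a tachogram; the delimited variant is used when labels matter.

    ``include_labels=None`` writes the delimited form only if any beat is
    not labelled ``normal``.  Floats are written with ``repr`` so a
    read-back is exact.
    """
    if include_labels is None:
        include_labels = bool(np.any(series.labels != NORMAL))
    stream, close = _open_maybe(destination, "w")
    try:
        if include_labels:
            stream.write("rr_ms,label\n")
            for v, lab in zip(series.values, series.labels):
                stream.write(f"{float(v)!r},{lab}\n")
        else:
            for v in series.values:
                stream.write(f"{float(v)!r}\n")
    finally:
        if close:
            stream.close()


def write_metrics_table(rows: Sequence[Mapping[str, object]], destination) -> None:
    """Write metric records as CSV with exact (repr) float formatting.

    All rows must share the key set of the first row; column order follows
    the first row's insertion order.
    """
    rows = list(rows)
    stream, close = _open_maybe(destination, "w")
    try:
        writer = csv.writer(stream, lineterminator="\n")
        if not rows:
            writer.writerow([])
            return
        keys = list(rows[0].keys())
        keyset = set(keys)
        for i, row in enumerate(rows):
            if set(row.keys()) != keyset:
                raise SchemaError(f"row {i} keys differ from row 0")
        writer.writerow(keys)
        for row in rows:
            writer.writerow([_format_cell(row[k]) for k in keys])
    finally:
        if close:
            stream.close()


def _format_cell(value: object) -> str:
    if isinstance(value, (float, np.floating)):
        return repr(float(value))
    if isinstance(value, (int, np.integer)) and not isinstance(value, bool):
        return str(int(value))
    return str(value)


def read_metrics_table(source) -> list[dict[str, object]]:
    """Read a metrics table written by :func:`write_metrics_table`.

    Cells are converted back to float when parseable, leaving other cells
    as strings.
    """
    stream, close = _open_maybe(source)
    try:
        reader = csv.reader(stream)
        rows = [r for r in reader if r and any(c.strip() for c in r)]
    finally:
        if close:
            stream.close()
    if not rows:
        return []
    keys = rows[0]
    out = []
    for r in rows[1:]:
        rec: dict[str, object] = {}
        for k, cell in zip(keys, r):
            try:
                rec[k] = float(cell)
            except ValueError:
                rec[k] = cell
        out.append(rec)
    return out
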