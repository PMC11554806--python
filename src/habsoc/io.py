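"""Reading, validating and writing RFID antenna event logs.

Event logs are plain CSV with header ``time_s,antenna,tag``: session-relative
time in decimal seconds, integer antenna id, opaque tag code.  Reading
validates rows against the apparatus and registry; rows that fail are
collected in a :class:`ValidationReport` rather than silently dropped.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .apparatus import AnimalRegistry, Apparatus

EVENT_COLUMNS = ("time_s", "antenna", "tag")

#: Default window for merging hardware re-reads of a stationary animal:
#: same tag at the same antenna within this many seconds keeps the first read.
DEFAULT_DEBOUNCE_S = 0.5

#: Timestamps out of order by at most this much are re-sorted (benign logger
#: jitter); larger disorder fails validation as a corrupted log.
DEFAULT_DISORDER_TOL_S = 0.1


class ParseError(ValueError):
    """A malformed row; the message names the 1-based line number."""


class ValidationError(ValueError):
    """Log-level validation failure (e.g. badly non-monotone timestamps)."""


@dataclass
class ValidationReport:
    """Per-log accounting of rejected and merged rows.

    ``n_input_rows`` always equals ``n_accepted`` plus the number of
    rejected rows plus the number of debounce-merged duplicates.
    """

    n_input_rows: int = 0
    n_accepted: int = 0
    unknown_tag_rows: list[int] = field(default_factory=list)
    unknown_antenna_rows: list[int] = field(default_factory=list)
    merged_duplicate_rows: list[int] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.unknown_tag_rows) + len(self.unknown_antenna_rows)

    @property
    def ok(self) -> bool:
        return self.n_rejected == 0

    def summary(self) -> str:
        return (
            f"{self.n_input_rows} rows: {self.n_accepted} accepted, "
            f"{len(self.unknown_tag_rows)} unknown tag, "
            f"{len(self.unknown_antenna_rows)} unknown antenna, "
            f"{len(self.merged_duplicate_rows)} duplicate reads merged"
        )


def empty_events() -> pd.DataFrame:
    return pd.DataFrame({
        "time_s": pd.Series(dtype=float),
        "antenna": pd.Series(dtype=int),
        "tag": pd.Series(dtype=str),
    })


def events_frame(times, antennas, tags) -> pd.DataFrame:
    """Assemble a sorted event table from parallel sequences."""
    df = pd.DataFrame({
        "time_s": np.asarray(times, dtype=float),
        "antenna": np.asarray(antennas, dtype=int),
        "tag": list(tags),
    })
    return df.sort_values("time_s", kind="stable", ignore_index=True)


def read_events(
    path: str | Path,
    apparatus: Apparatus,
    registry: AnimalRegistry,
    *,
    debounce_s: float = DEFAULT_DEBOUNCE_S,
    disorder_tol_s: float = DEFAULT_DISORDER_TOL_S,
) -> tuple[pd.DataFrame, ValidationReport]:
    """Read and validate an antenna event log.

    Returns the accepted events sorted by time together with a
    :class:`ValidationReport`.  Unknown tags/antennas are reported, not
    dropped silently; negative times or timestamp disorder beyond
    ``disorder_tol_s`` raise :class:`ValidationError`; malformed rows raise
    :class:`ParseError` naming the line.
    """
    report = ValidationReport()
    times: list[float] = []
    antennas: list[int] = []
    tags: list[str] = []
    row_lines: list[int] = []

    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration as exc:
            raise ParseError("line 1: missing header") from exc
        if [h.strip() for h in header] != list(EVENT_COLUMNS):
            raise ParseError(
                f"line 1: expected header {','.join(EVENT_COLUMNS)!r}, "
                f"got {','.join(header)!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 3:
                raise ParseError(f"line {lineno}: expected 3 fields, got {len(row)}")
            report.n_input_rows += 1
            try:
                t = float(row[0])
                antenna = int(row[1])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
            tag = row[2].strip()
            if t < 0:
                raise ValidationError(f"line {lineno}: negative time {t}")
            if antenna not in apparatus.antenna_map:
                report.unknown_antenna_rows.append(lineno)
                continue
            if tag not in registry:
                report.unknown_tag_rows.append(lineno)
                continue
            times.append(t)
            antennas.append(antenna)
            tags.append(tag)
            row_lines.append(lineno)

    arr = np.asarray(times, dtype=float)
    if arr.size:
        drop = np.minimum.accumulate(arr[::-1])[::-1]  # running min from right
        disorder = arr - drop
        worst = float(disorder.max())
        if worst > disorder_tol_s:
            i = int(disorder.argmax())
            raise ValidationError(
                f"line {row_lines[i]}: timestamp disorder {worst:.3f} s exceeds "
                f"tolerance {disorder_tol_s} s"
            )

    df = events_frame(times, antennas, tags)
    if debounce_s > 0 and len(df):
        df, merged_idx = _debounce(df, debounce_s)
        report.merged_duplicate_rows = [row_lines[i] for i in merged_idx]
    report.n_accepted = len(df)
    return df, report


def _debounce(df: pd.DataFrame, window_s: float) -> tuple[pd.DataFrame, list[int]]:
    """Merge repeat reads of the same tag at the same antenna within
    ``window_s`` of the last *kept* read, keeping the first."""
    last_kept: dict[tuple[str, int], float] = {}
    keep = np.ones(len(df), dtype=bool)
    merged: list[int] = []
    for i, (t, antenna, tag) in enumerate(
        zip(df["time_s"].to_numpy(), df["antenna"].to_numpy(), df["tag"])
    ):
        key = (tag, int(antenna))
        prev = last_kept.get(key)
        if prev is not None and t - prev < window_s:
            keep[i] = False
            merged.append(i)
        else:
            last_kept[key] = t
    return df[keep].reset_index(drop=True), merged


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    """Write events as CSV; round-trips field-for-field with
    :func:`read_events` (times printed with shortest exact decimal form)."""
    out = events.copy()
    out["time_s"] = [repr(float(t)) for t in out["time_s"]]
    out.to_csv(path, index=False, columns=list(EVENT_COLUMNS))


def read_visits(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"animal": str})
    expected = ["animal", "compartment", "start_s", "end_s"]
    if list(df.columns) != expected:
        raise ParseError(f"visits file must have columns {expected}")
    return df


def write_visits(visits: pd.DataFrame, path: str | Path) -> None:
    visits.to_csv(path, index=False,
                  columns=["animal", "compartment", "start_s", "end_s"])
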