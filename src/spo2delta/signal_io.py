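"""Reading, quality control and segmentation of 1 Hz SpO2 recordings.

A raw record may contain gaps (missing seconds) and out-of-range samples;
analysis operates on :class:`OximetrySegment` objects, which are by
construction contiguous, gap-free and in-range. Out-of-range values break a
valid run exactly as a missing second does: only noise-free series are
analysed and no imputation is performed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .exceptions import EmptyInputError, ExtractionError, FormatError

GROUP_LABELS = {"healthy", "sepsis", "copd", "alf", "cirrhosis", "synthetic", "other"}

#: Default required durations (seconds) by cohort convention:
#: 1200 s for ICU patients, 600 s for short recordings (acute liver failure),
#: 480 s for the final segment of each healthy hypoxia exposure.
DEFAULT_DURATIONS = {"patient": 1200, "short": 600, "reference": 480}


@dataclass(frozen=True)
class RawRecord:
    """A possibly-gappy 1 Hz SpO2 record as read from disk.

    ``timestamps`` are integer seconds from recording start, strictly
    increasing; ``values`` are percent saturation, retained verbatim even
    when out of the physiological [0, 100] range.
    """

    subject_id: str
    timestamps: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        if len(self.timestamps) != len(self.values):
            raise FormatError("timestamps and values have different lengths")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def n_gaps(self) -> int:
        """Missing seconds between the first and last timestamp."""
        if len(self) == 0:
            return 0
        span = int(self.timestamps[-1] - self.timestamps[0]) + 1
        return span - len(self)

    @property
    def out_of_range(self) -> np.ndarray:
        """Boolean mask of samples outside [0, 100] or non-finite."""
        with np.errstate(invalid="ignore"):
            return ~np.isfinite(self.values) | (self.values < 0) | (self.values > 100)

    @property
    def n_out_of_range(self) -> int:
        return int(self.out_of_range.sum())


@dataclass(frozen=True)
class OximetrySegment:
    """A contiguous, gap-free 1 Hz SpO2 segment for one subject."""

    subject_id: str
    values: np.ndarray
    group_label: str = "other"
    start_offset: int = 0

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or len(vals) < 2:
            raise ValueError("segment needs at least 2 samples")
        if not np.all(np.isfinite(vals)) or vals.min() < 0 or vals.max() > 100:
            raise ValueError("segment values must be finite and within [0, 100]")
        if self.group_label not in GROUP_LABELS:
            raise ValueError(f"unknown group label {self.group_label!r}")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def duration_s(self) -> int:
        return len(self.values)

    @property
    def mean_spo2(self) -> float:
        return float(np.mean(self.values))


@dataclass(frozen=True)
class QCReport:
    subject_id: str
    n_samples: int
    n_out_of_range: int
    n_gaps: int
    longest_valid_run_s: int
    required_duration_s: int
    passed: bool

    def to_json(self) -> str:
        return json.dumps(self.__dict__)


def read_spo2_csv(path: str | Path, subject_id: str | None = None) -> RawRecord:
    """Read a 1 Hz SpO2 export.

    Accepts a two-column ``t_s,spo2`` CSV (with or without header) or a
    single-column value-per-line file (WFDB-style numeric export), plain or
    gzip-compressed. Timestamps must be whole seconds, strictly increasing,
    without duplicates; out-of-range and missing entries are retained in the
    record and flagged downstream.
    """
    path = Path(path)
    if subject_id is None:
        subject_id = path.name.split(".")[0]
    try:
        df = pd.read_csv(path, header=None, comment="#", skip_blank_lines=True,
                         float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: no samples") from None
    except (ValueError, OSError) as exc:
        raise FormatError(f"{path}: {exc}") from exc

    # a textual header row makes the columns object-typed; re-read without it
    # so the parser converts floats directly (round-trip exact)
    if df.iloc[0].apply(lambda v: isinstance(v, str)).any():
        try:
            df = pd.read_csv(path, header=None, comment="#",
                             skip_blank_lines=True, skiprows=1,
                             float_precision="round_trip")
        except pd.errors.EmptyDataError:
            raise EmptyInputError(f"{path}: no samples") from None
    if df.empty:
        raise EmptyInputError(f"{path}: no samples")
    if not all(np.issubdtype(dt, np.number) for dt in df.dtypes):
        raise FormatError(f"{path}: non-numeric data")

    if df.shape[1] == 1:
        values = df.iloc[:, 0].to_numpy(dtype=float)
        timestamps = np.arange(len(values), dtype=np.int64)
    elif df.shape[1] == 2:
        t = df.iloc[:, 0].to_numpy(dtype=float)
        if not np.allclose(t, np.round(t)):
            raise FormatError(f"{path}: sub-second timestamps are not supported")
        timestamps = np.round(t).astype(np.int64)
        if np.any(np.diff(timestamps) == 0):
            raise FormatError(f"{path}: duplicated timestamps")
        if np.any(np.diff(timestamps) < 0):
            raise FormatError(f"{path}: timestamps not increasing")
        values = df.iloc[:, 1].to_numpy(dtype=float)
    else:
        raise FormatError(f"{path}: expected 1 or 2 columns, found {df.shape[1]}")
    return RawRecord(subject_id=subject_id, timestamps=timestamps, values=values)


def _valid_runs(record: RawRecord) -> list[tuple[int, int]]:
    """Maximal contiguous runs of in-range samples with consecutive timestamps.

    Returns (start_index, length) pairs in record index space. A gap in the
    timestamps or an out-of-range value terminates a run.
    """
    n = len(record)
    if n == 0:
        return []
    bad = record.out_of_range
    # boundary before sample i when timestamps jump or either side is bad
    breaks = np.zeros(n, dtype=bool)
    breaks[0] = True
    if n > 1:
        breaks[1:] = np.diff(record.timestamps) != 1
    runs: list[tuple[int, int]] = []
    start = None
    for i in range(n):
        if bad[i] or breaks[i]:
            if start is not None and i > start:
                runs.append((start, i - start))
            start = None if bad[i] else i
        elif start is None:
            start = i
    if start is not None:
        runs.append((start, n - start))
    return runs


def qc_record(record: RawRecord, required_duration_s: int) -> QCReport:
    """Quality-control report: does the record contain a contiguous,
    in-range, gap-free run of at least ``required_duration_s`` seconds?"""
    runs = _valid_runs(record)
    longest = max((length for _, length in runs), default=0)
    return QCReport(
        subject_id=record.subject_id,
        n_samples=len(record),
        n_out_of_range=record.n_out_of_range,
        n_gaps=record.n_gaps,
        longest_valid_run_s=longest,
        required_duration_s=required_duration_s,
        passed=longest >= required_duration_s,
    )


def extract_segment(
    record: RawRecord,
    duration_s: int,
    policy: Literal["earliest", "final"] = "earliest",
    group_label: str = "other",
) -> OximetrySegment:
    """Extract a contiguous valid segment of exactly ``duration_s`` samples.

    ``policy="earliest"`` takes the first ``duration_s`` samples of the
    earliest valid run long enough (patient convention: earliest available
    data of the first ICU day). ``policy="final"`` takes the last
    ``duration_s`` samples of the latest such run (reference convention: the
    final minutes of a hypoxia exposure, approximating a stable state).
    """
    if policy not in ("earliest", "final"):
        raise ValueError(f"unknown policy {policy!r}")
    runs = [(s, ln) for s, ln in _valid_runs(record) if ln >= duration_s]
    if not runs:
        longest = max((ln for _, ln in _valid_runs(record)), default=0)
        raise ExtractionError(
            f"{record.subject_id}: no valid run of {duration_s} s "
            f"(longest available: {longest} s)",
            longest_valid_run_s=longest,
        )
    if policy == "earliest":
        start, _ = runs[0]
        sl = slice(start, start + duration_s)
    else:
        start, length = runs[-1]
        sl = slice(start + length - duration_s, start + length)
    return OximetrySegment(
        subject_id=record.subject_id,
        values=record.values[sl].copy(),
        group_label=group_label,
        start_offset=int(record.timestamps[sl.start]),
    )


def write_segment_csv(segment: OximetrySegment, path: str | Path) -> None:
    """Write a segment as canonical two-column ``t_s,spo2`` CSV."""
    t = np.arange(segment.start_offset, segment.start_offset + len(segment))
    pd.DataFrame({"t_s": t, "spo2": segment.values}).to_csv(path, index=False)


def write_qc_log(reports: Sequence[QCReport], path: str | Path) -> None:
    """Append QC reports as JSON lines."""
    with open(path, "a") as fh:
        for rep in reports:
            fh.write(rep.to_json() + "\n")
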