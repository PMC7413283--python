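"""Activity-count records: data model, preprocessing and corruption.

Minute-level actigraphy counts are handled as one record per subject-day.
A full day has 1440 values (minute 0 = local midnight); after extraction of
the 9 AM - 9 PM waking window a record has 720 values.  Missingness
("nonwear") is represented by runs of consecutive zeros; a run of 30 minutes
or more counts as a missing interval.  Evaluation-time corruption overwrites
one random interval with zeros and remembers the positions in a boolean mask
so reconstruction error can be scored on exactly those cells.

All coordinates are 0-based with half-open [start, start + length) intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

FULL_DAY_MINUTES = 1440
WINDOW_START_MINUTE = 540   # 09:00
WINDOW_END_MINUTE = 1260    # 21:00
WINDOW_MINUTES = WINDOW_END_MINUTE - WINDOW_START_MINUTE  # 720
DEFAULT_MIN_RUN = 30

AXIS_KINDS = ("uniaxial", "magnitude")


@dataclass
class ActivityRecord:
    """One subject-day of nonnegative activity counts at one-minute epochs."""

    subject_id: str
    day_index: int
    values: np.ndarray
    axis_kind: str = "uniaxial"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("record values must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("record values must be finite")
        if np.any(self.values < 0):
            raise ValueError("activity counts must be nonnegative")
        if self.axis_kind not in AXIS_KINDS:
            raise ValueError(f"axis_kind must be one of {AXIS_KINDS}")

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass
class MissingMask:
    """Boolean flags marking the missing/imputed cells of a record (True = missing)."""

    flags: np.ndarray

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)
        if self.flags.ndim != 1:
            raise ValueError("mask flags must be one-dimensional")

    @classmethod
    def empty(cls, length: int) -> "MissingMask":
        return cls(np.zeros(length, dtype=bool))

    @classmethod
    def from_interval(cls, length: int, start: int, run_length: int) -> "MissingMask":
        if not (0 <= start and start + run_length <= length):
            raise ValueError("interval does not fit in record")
        flags = np.zeros(length, dtype=bool)
        flags[start : start + run_length] = True
        return cls(flags)

    def interval(self) -> tuple[int, int]:
        """(start, length) of the flagged run; requires one contiguous run."""
        idx = np.flatnonzero(self.flags)
        if idx.size == 0:
            raise ValueError("mask is empty")
        start, stop = int(idx[0]), int(idx[-1]) + 1
        if stop - start != idx.size:
            raise ValueError("mask is not one contiguous run")
        return start, stop - start

    def __len__(self) -> int:
        return self.flags.shape[0]


SPLIT_LABELS = ("train", "validation", "test")


@dataclass
class RecordSet:
    """A list of records with optional index-aligned masks and split labels."""

    records: list[ActivityRecord]
    masks: list[MissingMask] | None = None
    split_labels: list[str] | None = None

    def __post_init__(self) -> None:
        if self.masks is not None:
            if len(self.masks) != len(self.records):
                raise ValueError("masks must be index-aligned with records")
            for rec, mask in zip(self.records, self.masks):
                if len(rec) != len(mask):
                    raise ValueError("mask length must match its record")
        if self.split_labels is not None:
            if len(self.split_labels) != len(self.records):
                raise ValueError("split_labels must be index-aligned with records")
            for lab in self.split_labels:
                if lab not in SPLIT_LABELS:
                    raise ValueError(f"unknown split label {lab!r}")

    def __len__(self) -> int:
        return len(self.records)

    def values_matrix(self) -> np.ndarray:
        """(M, N) float matrix; requires all records the same length."""
        lengths = {len(r) for r in self.records}
        if len(lengths) != 1:
            raise ValueError("records have mixed lengths")
        return np.stack([r.values for r in self.records])

    def mask_matrix(self) -> np.ndarray:
        if self.masks is None:
            raise ValueError("record set has no masks")
        return np.stack([m.flags for m in self.masks])

    def subset(self, indices: Sequence[int]) -> "RecordSet":
        idx = list(indices)
        return RecordSet(
            records=[self.records[i] for i in idx],
            masks=None if self.masks is None else [self.masks[i] for i in idx],
            split_labels=None
            if self.split_labels is None
            else [self.split_labels[i] for i in idx],
        )

    def split(self, label: str) -> "RecordSet":
        if self.split_labels is None:
            raise ValueError("record set has no split labels")
        return self.subset([i for i, lab in enumerate(self.split_labels) if lab == label])


@dataclass
class CorruptionSpec:
    """A seeded, fixed-length zero-overwrite corruption."""

    interval_length: int = DEFAULT_MIN_RUN
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.interval_length < 1:
            raise ValueError("interval_length must be >= 1")


def magnitude_vector(x: float, y: float, z: float) -> float:
    """Euclidean magnitude sqrt(x^2 + y^2 + z^2) of a triaxial sample."""
    for v in (x, y, z):
        if not math.isfinite(v):
            raise ValueError("magnitude_vector requires finite inputs")
    return math.sqrt(x * x + y * y + z * z)


def downsample_to_minutes(samples: Sequence[float], rate_hz: float) -> np.ndarray:
    """Average a higher-rate count stream into per-minute values.

    ``rate_hz * 60`` must be a positive integer and the sample count an exact
    multiple of it: partial minutes are rejected, not padded.
    """
    per_minute = rate_hz * 60.0
    if per_minute <= 0 or abs(per_minute - round(per_minute)) > 1e-9:
        raise ValueError("rate_hz * 60 must be a positive integer")
    per_minute = int(round(per_minute))
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("samples must be a nonempty 1-D sequence")
    if arr.size % per_minute != 0:
        raise ValueError(
            f"sample count {arr.size} is not a multiple of {per_minute} samples/minute"
        )
    return arr.reshape(-1, per_minute).mean(axis=1)


def detect_missing_intervals(
    record: ActivityRecord | np.ndarray, min_run: int = DEFAULT_MIN_RUN
) -> list[tuple[int, int]]:
    """Maximal runs of exact zeros with length >= ``min_run``.

    Returns 0-based (start, length) pairs with half-open extent
    [start, start + length).
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    values = record.values if isinstance(record, ActivityRecord) else np.asarray(record)
    is_zero = values == 0
    if not is_zero.any():
        return []
    # run boundaries of the zero indicator
    padded = np.concatenate(([False], is_zero, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    stops = np.flatnonzero(diff == -1)
    return [
        (int(s), int(e - s)) for s, e in zip(starts, stops) if e - s >= min_run
    ]


def is_complete(
    record: ActivityRecord,
    min_run: int = DEFAULT_MIN_RUN,
    scope: str = "full_day",
) -> bool:
    """True iff the record contains no missing interval over the chosen scope."""
    if scope == "full_day":
        if len(record) != FULL_DAY_MINUTES:
            raise ValueError("full_day completeness requires a 1440-minute record")
        values = record.values
    elif scope == "window":
        if len(record) == FULL_DAY_MINUTES:
            values = record.values[WINDOW_START_MINUTE:WINDOW_END_MINUTE]
        elif len(record) == WINDOW_MINUTES:
            values = record.values
        else:
            raise ValueError("window completeness requires a 1440- or 720-minute record")
    else:
        raise ValueError("scope must be 'full_day' or 'window'")
    return not detect_missing_intervals(values, min_run)


def extract_window(
    record: ActivityRecord,
    start_minute: int = WINDOW_START_MINUTE,
    end_minute: int = WINDOW_END_MINUTE,
) -> ActivityRecord:
    """Slice the waking window (default 9 AM - 9 PM, positions [540, 1260))."""
    if len(record) != FULL_DAY_MINUTES:
        raise ValueError("window extraction requires a 1440-minute record")
    if not (0 <= start_minute < end_minute <= FULL_DAY_MINUTES):
        raise ValueError("invalid window bounds")
    return replace(record, values=record.values[start_minute:end_minute].copy())


def corrupt(
    record: ActivityRecord, spec: CorruptionSpec
) -> tuple[ActivityRecord, MissingMask]:
    """Overwrite one random interval with zeros; return corrupted copy and mask.

    The start index is drawn uniformly from [0, N - L] using ``spec.rng_seed``;
    the same record and seed always give the same interval.
    """
    n = len(record)
    length = spec.interval_length
    if length > n:
        raise ValueError("corruption interval longer than record")
    rng = np.random.default_rng(spec.rng_seed)
    start = int(rng.integers(0, n - length + 1))
    values = record.values.copy()
    values[start : start + length] = 0.0
    mask = MissingMask.from_interval(n, start, length)
    return replace(record, values=values), mask


def corrupt_set(
    record_set: RecordSet, interval_length: int, rng_seed: int
) -> RecordSet:
    """Corrupt every record with an independent seeded interval (fixed per record)."""
    root = np.random.default_rng(rng_seed)
    seeds = root.integers(0, 2**31 - 1, size=len(record_set))
    records, masks = [], []
    for rec, seed in zip(record_set.records, seeds):
        corrupted, mask = corrupt(rec, CorruptionSpec(interval_length, int(seed)))
        records.append(corrupted)
        masks.append(mask)
    return RecordSet(records, masks, record_set.split_labels)


# ---------------------------------------------------------------------------
# CSV I/O.  Wide format (canonical): subject_id, day_index, axis_kind,
# m0000..mNNNN.  Long format: subject_id, day_index, axis_kind, minute, count.
# Mask sidecar: subject_id, day_index, start, length.
# ---------------------------------------------------------------------------

def _minute_columns(n: int) -> list[str]:
    return [f"m{i:04d}" for i in range(n)]


def write_csv(record_set: RecordSet, path, fmt: str = "wide") -> None:
    if fmt == "wide":
        lengths = {len(r) for r in record_set.records}
        if len(lengths) != 1:
            raise ValueError("wide CSV requires records of equal length")
        n = lengths.pop()
        frame = pd.DataFrame(
            record_set.values_matrix(), columns=_minute_columns(n)
        )
        frame.insert(0, "subject_id", [r.subject_id for r in record_set.records])
        frame.insert(1, "day_index", [r.day_index for r in record_set.records])
        frame.insert(2, "axis_kind", [r.axis_kind for r in record_set.records])
        frame.to_csv(path, index=False)
    elif fmt == "long":
        rows = []
        for r in record_set.records:
            rows.append(
                pd.DataFrame(
                    {
                        "subject_id": r.subject_id,
                        "day_index": r.day_index,
                        "axis_kind": r.axis_kind,
                        "minute": np.arange(len(r)),
                        "count": r.values,
                    }
                )
            )
        pd.concat(rows, ignore_index=True).to_csv(path, index=False)
    else:
        raise ValueError("fmt must be 'wide' or 'long'")


def read_csv(path, fmt: str = "wide") -> RecordSet:
    frame = pd.read_csv(path)
    records: list[ActivityRecord] = []
    if fmt == "wide":
        minute_cols = [c for c in frame.columns if c.startswith("m") and c[1:].isdigit()]
        if not minute_cols:
            raise ValueError("no minute columns found in wide CSV")
        minute_cols.sort()
        if frame[minute_cols].isna().any().any():
            raise ValueError("missing cells are not allowed (represent gaps as zeros + masks)")
        for _, row in frame.iterrows():
            records.append(
                ActivityRecord(
                    subject_id=str(row["subject_id"]),
                    day_index=int(row["day_index"]),
                    values=row[minute_cols].to_numpy(dtype=float),
                    axis_kind=str(row.get("axis_kind", "uniaxial")),
                )
            )
    elif fmt == "long":
        if frame[["minute", "count"]].isna().any().any():
            raise ValueError("missing cells are not allowed (represent gaps as zeros + masks)")
        for (sid, day), grp in frame.groupby(["subject_id", "day_index"], sort=True):
            grp = grp.sort_values("minute")
            if not np.array_equal(grp["minute"].to_numpy(), np.arange(len(grp))):
                raise ValueError(f"record {sid}/{day} has gaps in its minute index")
            axis = str(grp["axis_kind"].iloc[0]) if "axis_kind" in grp else "uniaxial"
            records.append(
                ActivityRecord(
                    subject_id=str(sid),
                    day_index=int(day),
                    values=grp["count"].to_numpy(dtype=float),
                    axis_kind=axis,
                )
            )
    else:
        raise ValueError("fmt must be 'wide' or 'long'")
    return RecordSet(records)


def write_mask_sidecar(record_set: RecordSet, path) -> None:
    if record_set.masks is None:
        raise ValueError("record set has no masks")
    rows = []
    for rec, mask in zip(record_set.records, record_set.masks):
        start, length = mask.interval()
        rows.append(
            {
                "subject_id": rec.subject_id,
                "day_index": rec.day_index,
                "start": start,
                "length": length,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_mask_sidecar(record_set: RecordSet, path) -> RecordSet:
    frame = pd.read_csv(path)
    keyed = {
        (str(row["subject_id"]), int(row["day_index"])): (int(row["start"]), int(row["length"]))
        for _, row in frame.iterrows()
    }
    masks = []
    for rec in record_set.records:
        key = (rec.subject_id, rec.day_index)
        if key not in keyed:
            raise ValueError(f"no mask row for record {key}")
        start, length = keyed[key]
        masks.append(MissingMask.from_interval(len(rec), start, length))
    return RecordSet(record_set.records, masks, record_set.split_labels)
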