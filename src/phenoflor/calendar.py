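"""Flowering-calendar data model and validated CSV I/O.

A *flowering calendar* is a dense plants-by-weeks grid of non-negative
integer flower-bud counts for one (department, semester, accession) cell of
a census.  The interchange format is long-format CSV with one record per
plant and week; weeks in which a plant shows no buds may be omitted and are
zero-filled on read, matching the census convention that weeks without
flower buds are treated as zeros.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Required columns of the long-format census CSV, in canonical order.
BUD_COUNT_COLUMNS = (
    "department",
    "semester",
    "accession",
    "size_class",
    "plant_id",
    "week",
    "count",
)

SEMESTERS = ("1st", "2nd", "3rd", "4th")

#: Default number of census weeks per flowering semester (a six-month
#: November–April or May–October window).
DEFAULT_N_WEEKS = 26


class CalendarValidationError(ValueError):
    """A census table violates the calendar contract (bad count, week, key...)."""


def flowering_period_of(semester: str) -> str:
    """Map a flowering semester to its flowering period.

    The 1st and 3rd semesters (November–April) belong to FP I, the 2nd and
    4th (May–October) to FP II.
    """
    try:
        return {"1st": "FP I", "2nd": "FP II", "3rd": "FP I", "4th": "FP II"}[semester]
    except KeyError:
        raise CalendarValidationError(
            f"unknown semester {semester!r}; expected one of {SEMESTERS}"
        ) from None


@dataclass(frozen=True)
class FloralCalendar:
    """Dense plants-by-weeks grid of flower-bud counts for one census cell.

    Attributes
    ----------
    department, semester, accession, size_class
        Grouping labels of the cell. ``size_class`` is ``"LS"`` (long-size,
        tall) or ``"SS"`` (short-size).
    n_weeks
        Number of weekly censuses in the semester; weeks are 1-based.
    plant_ids
        One label per individual, aligned with the rows of ``counts``.
    counts
        ``(n_plants, n_weeks)`` integer array, zero-filled.
    """

    department: str
    semester: str
    accession: str
    size_class: str
    n_weeks: int
    plant_ids: tuple[str, ...]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.array_equal(counts, np.round(counts)):
                raise CalendarValidationError("counts must be integers")
        counts = counts.astype(np.int64).reshape(len(self.plant_ids), self.n_weeks)
        object.__setattr__(self, "counts", counts)
        if counts.shape != (len(self.plant_ids), self.n_weeks):
            raise CalendarValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.plant_ids)} plants x {self.n_weeks} weeks"
            )
        if counts.size and counts.min() < 0:
            raise CalendarValidationError("counts must be non-negative")

    @property
    def flowering_period(self) -> str:
        return flowering_period_of(self.semester)

    @property
    def n_plants(self) -> int:
        return len(self.plant_ids)

    def weekly_totals(self) -> np.ndarray:
        """Population totals per week (sum over plants)."""
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        """Long-format records (all weeks, including zero weeks)."""
        n_p, n_w = self.counts.shape
        return pd.DataFrame(
            {
                "department": self.department,
                "semester": self.semester,
                "accession": self.accession,
                "size_class": self.size_class,
                "plant_id": np.repeat(list(self.plant_ids), n_w),
                "week": np.tile(np.arange(1, n_w + 1), n_p),
                "count": self.counts.ravel(),
            }
        )


class DropResult(NamedTuple):
    """Outcome of removing non-flowering individuals from a calendar."""

    calendar: FloralCalendar
    n_removed: int
    all_empty: bool


def zero_fill(
    records: Mapping[str, Iterable[tuple[int, int]]], n_weeks: int
) -> tuple[tuple[str, ...], np.ndarray]:
    """Expand sparse per-plant ``(week, count)`` pairs into a dense grid.

    Unobserved weeks become zeros; observed values are preserved.  Raises
    :class:`CalendarValidationError` for weeks outside ``[1, n_weeks]`` or
    duplicate weeks within a plant.
    """
    plant_ids = tuple(records)
    grid = np.zeros((len(plant_ids), n_weeks), dtype=np.int64)
    for i, pid in enumerate(plant_ids):
        seen: set[int] = set()
        for week, count in records[pid]:
            if not 1 <= week <= n_weeks:
                raise CalendarValidationError(
                    f"plant {pid!r}: week {week} outside [1, {n_weeks}]"
                )
            if week in seen:
                raise CalendarValidationError(f"plant {pid!r}: duplicate week {week}")
            seen.add(week)
            grid[i, week - 1] = count
    return plant_ids, grid


def drop_nonflowering(cal: FloralCalendar) -> DropResult:
    """Remove individuals that never flowered during the semester.

    Plants whose entire weekly series is zero are excluded, mirroring the
    census rule that non-flowering individuals do not enter the descriptor
    analysis.  Idempotent.  An all-zero calendar yields an empty calendar
    with ``all_empty`` set (and a logged warning) rather than an error.
    """
    keep = cal.counts.sum(axis=1) > 0
    n_removed = int((~keep).sum())
    if n_removed == 0:
        return DropResult(cal, 0, False)
    out = replace(
        cal,
        plant_ids=tuple(pid for pid, k in zip(cal.plant_ids, keep) if k),
        counts=cal.counts[keep],
    )
    all_empty = out.n_plants == 0
    if all_empty:
        logger.warning(
            "calendar (%s, %s, %s): no plant flowered; calendar is empty",
            cal.department,
            cal.semester,
            cal.accession,
        )
    else:
        logger.info(
            "calendar (%s, %s, %s): excluded %d non-flowering plant(s)",
            cal.department,
            cal.semester,
            cal.accession,
            n_removed,
        )
    return DropResult(out, n_removed, all_empty)


def _validate_frame(df: pd.DataFrame, n_weeks: int) -> pd.DataFrame:
    missing = [c for c in BUD_COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise CalendarValidationError(f"missing column(s): {', '.join(missing)}")
    df = df.copy()
    # Row numbers refer to the CSV file: header is line 1.
    rows = df.index.to_numpy() + 2

    for col in ("week", "count"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() | (numeric != numeric.round())
        if bad.any():
            raise CalendarValidationError(
                f"non-integer {col} at row(s) {rows[bad.to_numpy()][:5].tolist()}"
            )
        df[col] = numeric.astype(np.int64)

    neg = df["count"] < 0
    if neg.any():
        raise CalendarValidationError(
            f"negative count at row(s) {rows[neg.to_numpy()][:5].tolist()}"
        )
    oob = (df["week"] < 1) | (df["week"] > n_weeks)
    if oob.any():
        raise CalendarValidationError(
            f"week outside [1, {n_weeks}] at row(s) {rows[oob.to_numpy()][:5].tolist()}"
        )
    bad_sem = ~df["semester"].isin(SEMESTERS)
    if bad_sem.any():
        raise CalendarValidationError(
            f"unknown semester at row(s) {rows[bad_sem.to_numpy()][:5].tolist()}"
        )
    key = ["department", "semester", "accession", "plant_id", "week"]
    dup = df.duplicated(subset=key, keep=False)
    if dup.any():
        raise CalendarValidationError(
            f"duplicate (plant, week) record at row(s) {rows[dup.to_numpy()][:5].tolist()}"
        )
    return df


def calendars_from_frame(df: pd.DataFrame, n_weeks: int) -> list[FloralCalendar]:
    """Group validated long-format records into one calendar per census cell."""
    df = _validate_frame(df, n_weeks)
    cals: list[FloralCalendar] = []
    for (dept, sem, acc), cell in df.groupby(
        ["department", "semester", "accession"], sort=True
    ):
        size_classes = cell["size_class"].unique()
        if len(size_classes) > 1:
            raise CalendarValidationError(
                f"cell ({dept}, {sem}, {acc}) mixes size classes {sorted(size_classes)}"
            )
        records = {
            str(pid): list(zip(sub["week"], sub["count"]))
            for pid, sub in cell.groupby("plant_id", sort=True)
        }
        plant_ids, grid = zero_fill(records, n_weeks)
        cals.append(
            FloralCalendar(
                department=str(dept),
                semester=str(sem),
                accession=str(acc),
                size_class=str(size_classes[0]),
                n_weeks=n_weeks,
                plant_ids=plant_ids,
                counts=grid,
            )
        )
    return cals


def read_bud_counts(
    path: str | Path, n_weeks: int = DEFAULT_N_WEEKS
) -> list[FloralCalendar]:
    """Read a long-format census CSV into validated flowering calendars.

    Parameters
    ----------
    path
        CSV with header ``department,semester,accession,size_class,plant_id,week,count``.
    n_weeks
        Width of the semester grid; weeks absent from the file are zeros.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return calendars_from_frame(df, n_weeks)


def write_bud_counts(
    cals: Sequence[FloralCalendar], path: str | Path, sparse: bool = False
) -> None:
    """Write calendars back to the long-format CSV.

    With ``sparse=True`` zero-count weeks are omitted (they are recovered by
    zero-filling on read); otherwise the full grid is written so a read
    round-trips bit-exactly even for all-zero plants.
    """
    frames = [c.to_frame() for c in cals]
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=list(BUD_COUNT_COLUMNS))
    )
    if sparse:
        df = df[df["count"] > 0]
    df.to_csv(path, index=False, columns=list(BUD_COUNT_COLUMNS))
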