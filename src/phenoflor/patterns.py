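"""Newstrom flowering-pattern classification.

Newstrom's taxonomy classes a multi-year flowering record by the frequency
of its flowering cycles: *continual* (flowering essentially year-round with
brief sporadic pauses), *sub-annual* (more than one cycle per year),
*annual* (one main cycle per year) and *supra-annual* (one cycle spanning
more than one year).  The taxonomy is qualitative; this module pins it to
explicit, configurable numeric rules that are reported alongside the label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .calendar import DEFAULT_N_WEEKS

#: Weeks per approximate month on the week grid (no calendar dates exist in
#: the data model, so months are consecutive 4-week blocks).
WEEKS_PER_MONTH = 4


@dataclass(frozen=True)
class PatternClass:
    """A Newstrom label together with the evidence it rests on."""

    label: str  # continual | sub-annual | annual | supra-annual | none
    n_cycles: int
    cycles_per_year: float
    longest_pause_weeks: int
    months_flowering: int
    n_months: int
    gap_weeks: int
    cycle_gap: int
    month_coverage: float


def _flowering_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of consecutive flowering weeks as (start, stop) slices."""
    runs: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(mask):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(mask)))
    return runs


def classify_newstrom(
    series: Sequence[float],
    weeks_per_semester: int = DEFAULT_N_WEEKS,
    gap_weeks: int = 4,
    cycle_gap: int = 8,
    month_coverage: float = 0.8,
) -> PatternClass:
    """Assign a Newstrom flowering-pattern class to a weekly total series.

    Parameters
    ----------
    series
        Population weekly bud totals spanning an integer number of
        semesters (two semesters = one year).
    weeks_per_semester
        Width of each semester block in the series.
    gap_weeks
        Longest pause (consecutive zero weeks between flowering) tolerated
        by the *continual* class.
    cycle_gap
        Minimum number of zero weeks separating two flowering cycles;
        shorter gaps are pauses within a single cycle.
    month_coverage
        Minimum fraction of (4-week) months with flowering required for
        the *continual* class.

    Notes
    -----
    Decision order: an all-zero record is *none*; a record flowering in at
    least ``month_coverage`` of months with no pause longer than
    ``gap_weeks`` is *continual* (taking precedence over *sub-annual*); a
    single cycle spanning more than one year is *supra-annual*; more than
    one cycle per year is *sub-annual*; otherwise *annual*.  The label is
    invariant under positive scaling of the series.
    """
    series = np.asarray(series, dtype=float)
    if gap_weeks <= 0 or cycle_gap <= 0:
        raise ValueError("thresholds must be positive")
    if series.size == 0 or series.size % weeks_per_semester:
        raise ValueError(
            f"series length {series.size} is not a positive multiple of "
            f"weeks_per_semester={weeks_per_semester}"
        )
    n_semesters = series.size // weeks_per_semester
    n_years = max(1.0, n_semesters / 2.0)
    year_weeks = 2 * weeks_per_semester
    n_months = math.ceil(series.size / WEEKS_PER_MONTH)

    mask = series > 0
    runs = _flowering_runs(mask)
    if not runs:
        return PatternClass(
            "none", 0, 0.0, 0, 0, n_months, gap_weeks, cycle_gap, month_coverage
        )

    # Merge flowering runs separated by fewer than cycle_gap zero weeks.
    cycles: list[tuple[int, int]] = [runs[0]]
    for start, stop in runs[1:]:
        if start - cycles[-1][1] < cycle_gap:
            cycles[-1] = (cycles[-1][0], stop)
        else:
            cycles.append((start, stop))

    # Longest pause between the first and last flowering week.
    pauses = [b[0] - a[1] for a, b in zip(runs, runs[1:])]
    longest_pause = max(pauses, default=0)

    months_flowering = sum(
        mask[m * WEEKS_PER_MONTH : (m + 1) * WEEKS_PER_MONTH].any()
        for m in range(n_months)
    )
    cycles_per_year = len(cycles) / n_years

    if (
        months_flowering / n_months >= month_coverage
        and longest_pause <= gap_weeks
    ):
        label = "continual"
    elif len(cycles) == 1 and cycles[0][1] - cycles[0][0] > year_weeks:
        label = "supra-annual"
    elif cycles_per_year > 1:
        label = "sub-annual"
    else:
        label = "annual"
    return PatternClass(
        label,
        len(cycles),
        cycles_per_year,
        int(longest_pause),
        int(months_flowering),
        n_months,
        gap_weeks,
        cycle_gap,
        month_coverage,
    )


def flowering_period_share(
    series: Sequence[float], weeks_per_semester: int = DEFAULT_N_WEEKS
) -> tuple[float, float]:
    """Fraction of a year's buds falling in each flowering period.

    ``series`` covers one year as an FP I semester followed by an FP II
    semester.  Returns ``(share_FPI, share_FPII)``; the shares sum to 1.

    Raises
    ------
    ValueError
        If the year has no buds at all (shares undefined) or the series is
        not exactly two semesters long.
    """
    series = np.asarray(series, dtype=float)
    if series.size != 2 * weeks_per_semester:
        raise ValueError(
            f"expected one year = {2 * weeks_per_semester} weeks, got {series.size}"
        )
    total = series.sum()
    if total <= 0:
        raise ValueError("flowering-period shares undefined: zero total buds")
    fp1 = float(series[:weeks_per_semester].sum() / total)
    return fp1, 1.0 - fp1
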