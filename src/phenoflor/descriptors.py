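"""Phenological flowering descriptors.

Three descriptors summarise a flowering calendar:

* ``r_i`` — synchrony among individuals: the mean of the absolute values of
  all pairwise Spearman rank correlations between individuals' weekly
  bud-count series. High when plants flower together, regardless of the
  direction or magnitude of the shared pulses.
* ``CV_i`` — intraindividual temporal variability: the mean over individuals
  of each plant's coefficient of variation (sd / mean) of weekly counts
  across the semester. High for few, tall, isolated pulses; low for evenly
  spread flowering.
* ``Event`` — the number of weeks in which the population (any individual of
  the accession) shows at least one flower bud.
"""

from __future__ import annotations

import logging
import math
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calendar import FloralCalendar, drop_nonflowering

logger = logging.getLogger(__name__)

CvDenominator = Literal["n-1", "n"]


class DescriptorError(ValueError):
    """A descriptor is undefined for the given calendar (too few plants...)."""


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with mid-rank (average) treatment of ties.

    Returns NaN when either series has zero variance (all values tied), in
    which case the correlation is undefined and the caller decides policy.

    Raises
    ------
    ValueError
        If the series differ in length or are shorter than 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def synchrony_ri(cal: FloralCalendar) -> tuple[float, int, int]:
    """Flowering synchrony among individuals.

    Averages ``|rho|`` over all unordered pairs of flowering plants.  Pairs
    for which the Spearman correlation is undefined (a constant series) are
    excluded from the average and counted.

    Returns
    -------
    (r_i, n_pairs_used, n_pairs_dropped)
        ``r_i`` is NaN if every pair is undefined.

    Raises
    ------
    DescriptorError
        If fewer than 2 plants flowered.
    """
    counts = drop_nonflowering(cal).calendar.counts
    n = counts.shape[0]
    if n < 2:
        raise DescriptorError(
            f"synchrony requires >= 2 flowering plants, got {n} in cell "
            f"({cal.department}, {cal.semester}, {cal.accession})"
        )
    used = dropped = 0
    total = 0.0
    for i, j in combinations(range(n), 2):
        rho = spearman_rho(counts[i], counts[j])
        if math.isnan(rho):
            dropped += 1
        else:
            used += 1
            total += abs(rho)
    if used == 0:
        logger.warning(
            "all %d plant pairs undefined in cell (%s, %s, %s); r_i is NaN",
            dropped,
            cal.department,
            cal.semester,
            cal.accession,
        )
        return math.nan, 0, dropped
    return total / used, used, dropped


def individual_cv(
    x: Sequence[float], denominator: CvDenominator = "n-1"
) -> float:
    """Coefficient of variation (sd / mean) of one plant's weekly counts.

    The sample standard deviation (``n-1``) is the default convention; the
    population form (``n``) is available as an alternative. A single
    positive spike among ``n`` otherwise-zero weeks gives CV = sqrt(n) under
    the sample convention.

    Raises
    ------
    ValueError
        For series shorter than 2 or with non-positive mean (an all-zero
        plant should have been excluded upstream).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 weeks")
    mean = x.mean()
    if mean <= 0:
        raise ValueError("CV undefined for a series with non-positive mean")
    ddof = 1 if denominator == "n-1" else 0
    return float(x.std(ddof=ddof) / mean)


def temporal_variability_cvi(
    cal: FloralCalendar, denominator: CvDenominator = "n-1"
) -> float:
    """Intraindividual temporal variability: mean of per-plant CVs.

    Raises
    ------
    DescriptorError
        If no plant flowered.
    """
    counts = drop_nonflowering(cal).calendar.counts
    if counts.shape[0] == 0:
        raise DescriptorError(
            f"CV_i requires >= 1 flowering plant in cell "
            f"({cal.department}, {cal.semester}, {cal.accession})"
        )
    return float(
        np.mean([individual_cv(row, denominator) for row in counts])
    )


def count_events(cal: FloralCalendar) -> int:
    """Number of flowering events: weeks with at least one bud population-wide."""
    if cal.n_plants == 0:
        return 0
    return int((cal.weekly_totals() > 0).sum())


def descriptor_table(
    cals: Sequence[FloralCalendar], cv_denominator: CvDenominator = "n-1"
) -> pd.DataFrame:
    """Assemble the descriptor response table, one row per calendar.

    Cells whose descriptors are undefined (fewer than two flowering plants)
    are kept as flagged rows with NaN descriptors rather than silently
    dropped. Rows are ordered by (department, semester, accession).
    """
    rows = []
    for cal in cals:
        row: dict[str, object] = {
            "department": cal.department,
            "semester": cal.semester,
            "flowering_period": cal.flowering_period,
            "accession": cal.accession,
            "size_class": cal.size_class,
        }
        kept = drop_nonflowering(cal).calendar
        n = kept.n_plants
        row["n_plants"] = n
        row["event"] = count_events(cal)
        try:
            ri, used, dropped = synchrony_ri(cal)
            row.update(r_i=ri, n_pairs_used=used, n_pairs_dropped=dropped)
        except DescriptorError as exc:
            logger.warning("descriptor undefined: %s", exc)
            row.update(r_i=math.nan, n_pairs_used=0, n_pairs_dropped=0)
        try:
            row["cv_i"] = temporal_variability_cvi(cal, cv_denominator)
        except DescriptorError:
            row["cv_i"] = math.nan
        row["flagged"] = math.isnan(row["r_i"]) or math.isnan(row["cv_i"])  # type: ignore[arg-type]
        rows.append(row)
    columns = [
        "department",
        "semester",
        "flowering_period",
        "accession",
        "size_class",
        "r_i",
        "cv_i",
        "event",
        "n_plants",
        "n_pairs_used",
        "n_pairs_dropped",
        "flagged",
    ]
    table = pd.DataFrame(rows, columns=columns)
    return table.sort_values(
        ["department", "semester", "accession"], kind="mergesort"
    ).reset_index(drop=True)
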