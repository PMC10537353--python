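"""Published semester climate summaries for the four study departments.

The package ships the meteorological summary of the four Colombian
experimental stations (Cesar, Caldas, Quindio, Cauca) over the four
flowering semesters of the study, as printed: mean/max/min air temperature
(degC), accumulated daily insolation, accumulated day length, accumulated
rainfall (mm) and days with rain.  Note: the published summary labels the
day-length column's units as W m-2, which conflicts with its description
as accumulated light hours; the numbers are stored as printed, without
correcting the unit label.

Departmental means are *recomputed* from the four semester rows, rounding
half-away-from-zero at the printed precision (1 decimal for temperatures,
integers otherwise) — the only convention consistent with every printed
mean — and can be checked against the stored printed means.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import pandas as pd

CLIMATE_VARIABLES = (
    "temp_mean",
    "temp_max",
    "temp_min",
    "insolation",
    "daylength",
    "rainfall",
    "days_rain",
)

#: Decimal places printed per variable.
_PRECISION = {
    "temp_mean": 1,
    "temp_max": 1,
    "temp_min": 1,
    "insolation": 0,
    "daylength": 0,
    "rainfall": 0,
    "days_rain": 0,
}

DEPARTMENTS = ("Cesar", "Caldas", "Quindio", "Cauca")


def _raw_table() -> pd.DataFrame:
    path = resources.files("phenoflor.data") / "climate_semesters.csv"
    with path.open() as fh:
        # Read as strings so half-unit decimals stay exact for rounding.
        return pd.read_csv(fh, dtype=str)


def load_climate_table() -> pd.DataFrame:
    """The 16 semester climate records (4 departments x 4 semesters)."""
    df = _raw_table()
    df = df[df["semester"] != "Mean"].reset_index(drop=True)
    out = df.copy()
    for var in CLIMATE_VARIABLES:
        out[var] = pd.to_numeric(out[var])
    assert len(out) == 16
    bad = ~((out["temp_min"] <= out["temp_mean"]) & (out["temp_mean"] <= out["temp_max"]))
    assert not bad.any(), "temperature ordering violated in climate fixture"
    return out


def load_printed_means() -> pd.DataFrame:
    """The printed departmental mean rows, as published."""
    df = _raw_table()
    df = df[df["semester"] == "Mean"].reset_index(drop=True)
    for var in CLIMATE_VARIABLES:
        df[var] = pd.to_numeric(df[var])
    return df.drop(columns="semester")


def climate_semester_means(department: str, variable: str) -> float:
    """Mean of a climate variable over the four semesters of a department.

    Rounded half-away-from-zero at the printed precision, using exact
    decimal arithmetic (binary floats misround half-unit averages such as
    107.5 or 75920.5).
    """
    if department not in DEPARTMENTS:
        raise KeyError(
            f"unknown department {department!r}; expected one of {DEPARTMENTS}"
        )
    if variable not in CLIMATE_VARIABLES:
        raise KeyError(
            f"unknown variable {variable!r}; expected one of {CLIMATE_VARIABLES}"
        )
    df = _raw_table()
    rows = df[(df["department"] == department) & (df["semester"] != "Mean")]
    mean = sum(Decimal(v) for v in rows[variable]) / Decimal(len(rows))
    quantum = Decimal(1).scaleb(-_PRECISION[variable])
    return float(mean.quantize(quantum, rounding=ROUND_HALF_UP))
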