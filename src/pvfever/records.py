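"""Record schemas and CSV I/O for the three longitudinal streams.

The pipeline consumes three comma-separated, UTF-8, headered streams:

* ``temperatures.csv`` — columns ``child_id, time_h, temp_c``; one caregiver
  measurement, time in hours since the child's anchoring vaccination.
* ``vaccinations.csv`` — columns ``child_id, vaccine, time_iso8601,
  age_months, weight_kg, sex``; one vaccination instant with demographics.
  Demographics may be blank (such records are dropped by the cascade, not at
  load time).
* ``doses.csv`` — columns ``child_id, agent, dose, time_h``; one antipyretic
  administration, time in hours since the anchoring vaccination.

Loading is row-tolerant: a malformed header or missing file is fatal, but a
row that violates a field constraint (e.g. a physically implausible
temperature) is rejected with its row number and a reason, and loading
continues.  ``accepted + rejected == input rows`` always holds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

#: The twelve-vaccine vocabulary. Combination single-shot vaccines (DTaP, MMR)
#: count as single vaccinations.
VACCINES: Tuple[str, ...] = (
    "BCG",
    "chickenpox",
    "DTaP",
    "hepatitis B",
    "hepatitis A",
    "Hib",
    "influenza",
    "Japanese encephalitis",
    "MMR",
    "pneumococcus",
    "polio",
    "rotavirus",
)

SEXES: Tuple[str, ...] = ("male", "female")

#: Plausibility bounds for a caregiver-entered body temperature, °C.
TEMP_MIN_C = 34.0
TEMP_MAX_C = 43.0

TEMPERATURE_COLUMNS = ["child_id", "time_h", "temp_c"]
VACCINATION_COLUMNS = ["child_id", "vaccine", "time_iso8601", "age_months", "weight_kg", "sex"]
DOSE_COLUMNS = ["child_id", "agent", "dose", "time_h"]


@dataclass(frozen=True)
class TemperatureReading:
    """One caregiver temperature measurement."""

    child_id: str
    time_h: float  # hours since the anchoring vaccination
    temp_c: float


@dataclass(frozen=True)
class VaccinationEvent:
    """One vaccination instant; anchor of the observation window."""

    child_id: str
    vaccine: str
    time_iso8601: str
    age_months: Optional[float]
    weight_kg: Optional[float]
    sex: Optional[str]


@dataclass(frozen=True)
class AntipyreticDose:
    """One antipyretic administration (dose units are carried opaquely)."""

    child_id: str
    agent: str
    dose: float
    time_h: float


class SchemaError(ValueError):
    """Fatal schema problem: missing file or malformed header."""


@dataclass
class LoadReport:
    """Bookkeeping for one loaded stream."""

    n_input: int
    n_accepted: int
    rejections: pd.DataFrame  # columns: row, reason

    @property
    def n_rejected(self) -> int:
        return len(self.rejections)


def _read_csv(path, expected_columns: List[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != expected_columns:
        raise SchemaError(
            f"{path}: malformed header {list(df.columns)!r}; expected {expected_columns!r}"
        )
    return df


def _to_float(s: str) -> float:
    v = float(s)
    if not math.isfinite(v):
        raise ValueError("not finite")
    return v


def load_temperatures(path) -> Tuple[pd.DataFrame, LoadReport]:
    """Load and validate a temperature stream.

    Returns the accepted readings (columns ``child_id, time_h, temp_c``, with
    numeric dtypes, input order preserved) and a :class:`LoadReport`.
    """
    raw = _read_csv(path, TEMPERATURE_COLUMNS)
    rows, rej = [], []
    for i, r in enumerate(raw.itertuples(index=False)):
        try:
            t = _to_float(r.time_h)
        except ValueError:
            rej.append((i, "time not a finite number"))
            continue
        try:
            temp = _to_float(r.temp_c)
        except ValueError:
            rej.append((i, "temperature not a finite number"))
            continue
        if not (TEMP_MIN_C <= temp <= TEMP_MAX_C):
            rej.append((i, "temperature out of bounds"))
            continue
        if not r.child_id:
            rej.append((i, "missing child_id"))
            continue
        rows.append((r.child_id, t, temp))
    df = pd.DataFrame(rows, columns=TEMPERATURE_COLUMNS)
    df["time_h"] = df["time_h"].astype(float)
    df["temp_c"] = df["temp_c"].astype(float)
    return df, LoadReport(len(raw), len(df), pd.DataFrame(rej, columns=["row", "reason"]))


def load_vaccinations(path) -> Tuple[pd.DataFrame, LoadReport]:
    """Load and validate a vaccination stream.

    Demographics may be blank (stored as NaN / None); records lacking them
    are filtered downstream by the cascade rather than rejected here.
    """
    raw = _read_csv(path, VACCINATION_COLUMNS)
    rows, rej = [], []
    for i, r in enumerate(raw.itertuples(index=False)):
        if not r.child_id:
            rej.append((i, "missing child_id"))
            continue
        if r.vaccine not in VACCINES:
            rej.append((i, "unknown vaccine"))
            continue
        try:
            ts = pd.Timestamp(r.time_iso8601)
            if pd.isna(ts):
                raise ValueError
        except ValueError:
            rej.append((i, "unparseable timestamp"))
            continue
        age = weight = np.nan
        sex = None
        if r.age_months:
            try:
                age = _to_float(r.age_months)
            except ValueError:
                rej.append((i, "age not a number"))
                continue
            if age < 0:
                rej.append((i, "negative age"))
                continue
        if r.weight_kg:
            try:
                weight = _to_float(r.weight_kg)
            except ValueError:
                rej.append((i, "weight not a number"))
                continue
            if weight <= 0:
                rej.append((i, "non-positive weight"))
                continue
        if r.sex:
            if r.sex not in SEXES:
                rej.append((i, "unknown sex code"))
                continue
            sex = r.sex
        rows.append((r.child_id, r.vaccine, r.time_iso8601, age, weight, sex))
    df = pd.DataFrame(rows, columns=VACCINATION_COLUMNS)
    df["age_months"] = df["age_months"].astype(float)
    df["weight_kg"] = df["weight_kg"].astype(float)
    return df, LoadReport(len(raw), len(df), pd.DataFrame(rej, columns=["row", "reason"]))


def load_doses(path) -> Tuple[pd.DataFrame, LoadReport]:
    """Load and validate an antipyretic-dose stream."""
    raw = _read_csv(path, DOSE_COLUMNS)
    rows, rej = [], []
    for i, r in enumerate(raw.itertuples(index=False)):
        if not r.child_id:
            rej.append((i, "missing child_id"))
            continue
        try:
            t = _to_float(r.time_h)
        except ValueError:
            rej.append((i, "time not a finite number"))
            continue
        try:
            dose = _to_float(r.dose)
        except ValueError:
            rej.append((i, "dose not a number"))
            continue
        if dose <= 0:
            rej.append((i, "non-positive dose"))
            continue
        rows.append((r.child_id, r.agent, dose, t))
    df = pd.DataFrame(rows, columns=DOSE_COLUMNS)
    df["dose"] = df["dose"].astype(float)
    df["time_h"] = df["time_h"].astype(float)
    return df, LoadReport(len(raw), len(df), pd.DataFrame(rej, columns=["row", "reason"]))


def load_records(
    path_temperatures, path_vaccinations, path_doses
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Load all three streams.

    Returns ``(readings, events, doses, reports)`` where ``reports`` maps the
    stream name to its :class:`LoadReport`.
    """
    readings, rep_t = load_temperatures(path_temperatures)
    events, rep_v = load_vaccinations(path_vaccinations)
    doses, rep_d = load_doses(path_doses)
    reports = {"temperatures": rep_t, "vaccinations": rep_v, "doses": rep_d}
    return readings, events, doses, reports


def _format_float(v) -> str:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return ""
    return repr(float(v))


def write_temperatures(df: pd.DataFrame, path) -> None:
    """Write a temperature stream so that a reload reproduces it exactly.

    Floats are written with ``repr`` so the round-trip is bit-faithful.
    """
    _write(df, path, TEMPERATURE_COLUMNS, float_cols=("time_h", "temp_c"))


def write_vaccinations(df: pd.DataFrame, path) -> None:
    _write(df, path, VACCINATION_COLUMNS, float_cols=("age_months", "weight_kg"))


def write_doses(df: pd.DataFrame, path) -> None:
    _write(df, path, DOSE_COLUMNS, float_cols=("dose", "time_h"))


def _write(df: pd.DataFrame, path, columns: List[str], float_cols=()) -> None:
    out = df.loc[:, columns].copy()
    for c in float_cols:
        out[c] = out[c].map(_format_float)
    for c in columns:
        if c not in float_cols:
            out[c] = out[c].map(lambda v: "" if v is None or (isinstance(v, float) and math.isnan(v)) else str(v))
    out.to_csv(path, index=False, lineterminator="\n")


def to_reading_records(df: pd.DataFrame) -> List[TemperatureReading]:
    return [TemperatureReading(r.child_id, r.time_h, r.temp_c) for r in df.itertuples(index=False)]


def to_vaccination_records(df: pd.DataFrame) -> List[VaccinationEvent]:
    return [
        VaccinationEvent(r.child_id, r.vaccine, r.time_iso8601,
                         None if pd.isna(r.age_months) else r.age_months,
                         None if pd.isna(r.weight_kg) else r.weight_kg,
                         r.sex if r.sex else None)
        for r in df.itertuples(index=False)
    ]


def to_dose_records(df: pd.DataFrame) -> List[AntipyreticDose]:
    return [AntipyreticDose(r.child_id, r.agent, r.dose, r.time_h) for r in df.itertuples(index=False)]
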