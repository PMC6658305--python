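"""Antipyretic administration patterns.

Two analyses of caregiver dosing behaviour after vaccination:

* timing of the first antipyretic dose — hourly histogram and cumulative
  fraction over the 48 h window;
* the body temperature at which the (first) dose was given, read off the
  piecewise-linear imputed curve at the dose time, binned at 0.1 °C.

A dose that falls outside its record's reading span is located via the
nearest reading if one lies within 1 h; otherwise it is counted as
*unlocatable* and excluded from the temperature distribution (but not from
the timing analysis).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .config import AnalysisConfig, DEFAULT_CONFIG
from .episodes import impute_linear, window_readings

#: Maximum gap (hours) between a dose outside the reading span and the
#: nearest reading for the dose temperature to still be located.
FALLBACK_MAX_GAP_H = 1.0


@dataclass(frozen=True)
class DoseContext:
    """One located dose: when it was given and at what temperature."""

    child_id: str
    time_h: float
    temperature_at_dose: Optional[float]
    is_first_dose: bool


def round_to_tenth(x: float) -> float:
    """Round to one decimal with half-away-from-zero ties (38.05 -> 38.1)."""
    return float(np.floor(abs(x) * 10.0 + 0.5) / 10.0 * np.sign(x)) if x else 0.0


def first_doses(
    records: pd.DataFrame, doses: pd.DataFrame, config: AnalysisConfig = DEFAULT_CONFIG
) -> pd.DataFrame:
    """First in-window dose per analyzable record (records without doses drop out)."""
    if records.empty or doses.empty:
        return pd.DataFrame(columns=["child_id", "time_h"])
    sub = doses.loc[
        (doses["time_h"] >= 0.0) & (doses["time_h"] <= config.window_hours)]
    firsts = sub.groupby("child_id", sort=False)["time_h"].min().reset_index()
    return firsts.loc[firsts["child_id"].isin(set(records["child_id"]))].reset_index(drop=True)


def first_dose_timing(
    first_dose_times: np.ndarray, config: AnalysisConfig = DEFAULT_CONFIG
) -> pd.DataFrame:
    """Hourly histogram and cumulative fraction of first-dose times.

    Bin ``h`` covers ``[h, h+1)`` hours post vaccination (the final bin is
    closed at the window edge). Fractions sum to 1 over doses in the window.
    """
    t = np.asarray(first_dose_times, float)
    n_hours = int(np.ceil(config.window_hours))
    edges = np.arange(0.0, n_hours + 1.0)
    counts, _ = np.histogram(np.clip(t, 0.0, n_hours - 1e-9), bins=edges)
    total = counts.sum()
    frac = counts / total if total else np.zeros_like(counts, dtype=float)
    return pd.DataFrame({
        "hour": edges[:-1].astype(int),
        "count": counts,
        "fraction": frac,
        "cumulative_fraction": np.cumsum(frac),
    })


def locate_dose_temperatures(
    records: pd.DataFrame,
    readings: pd.DataFrame,
    doses: pd.DataFrame,
    config: AnalysisConfig = DEFAULT_CONFIG,
    all_doses: bool = False,
) -> Tuple[pd.DataFrame, int]:
    """Temperature at dose time for each (first) dose of each record.

    The temperature is the imputed curve evaluated at the dose time; outside
    the reading span the nearest reading within 1 h is used; otherwise the
    dose is unlocatable. Returns ``(located, n_unlocatable)`` where
    ``located`` has columns ``child_id, time_h, temperature_at_dose``.
    """
    if records.empty or doses.empty:
        return pd.DataFrame(columns=["child_id", "time_h", "temperature_at_dose"]), 0
    keep = set(records["child_id"])
    sub = doses.loc[
        doses["child_id"].isin(keep)
        & (doses["time_h"] >= 0.0) & (doses["time_h"] <= config.window_hours)]
    if not all_doses:
        idx = sub.groupby("child_id", sort=False)["time_h"].idxmin()
        sub = sub.loc[idx]
    readings_by_child = {k: v for k, v in readings.groupby("child_id")}

    rows, unlocatable = [], 0
    for d in sub.itertuples(index=False):
        r = readings_by_child.get(d.child_id)
        temp = None
        if r is not None:
            t, y, _ = window_readings(r["time_h"].to_numpy(), r["temp_c"].to_numpy(), config)
            if len(t) >= 2 and t[0] <= d.time_h <= t[-1]:
                temp = float(impute_linear(t, y)(d.time_h))
            elif len(t) >= 1:
                gap = np.abs(t - d.time_h)
                j = int(np.argmin(gap))
                if gap[j] <= FALLBACK_MAX_GAP_H:
                    temp = float(y[j])
        if temp is None:
            unlocatable += 1
        else:
            rows.append((d.child_id, float(d.time_h), temp))
    return pd.DataFrame(rows, columns=["child_id", "time_h", "temperature_at_dose"]), unlocatable


def temperature_at_dose_distribution(
    records: pd.DataFrame,
    readings: pd.DataFrame,
    doses: pd.DataFrame,
    config: AnalysisConfig = DEFAULT_CONFIG,
    all_doses: bool = False,
) -> Dict[str, object]:
    """Distribution of body temperature at (first) antipyretic dose.

    Returns a dict with the 0.1 °C-binned counts (DataFrame ``bin_c,
    count``), the number of located and unlocatable doses, and the fractions
    of located doses at or above the fever threshold, below 37.0 °C and
    above 40.0 °C.
    """
    located, unlocatable = locate_dose_temperatures(records, readings, doses, config, all_doses)
    if located.empty:
        bins = pd.DataFrame(columns=["bin_c", "count"])
        return dict(bins=bins, n_located=0, n_unlocatable=unlocatable,
                    fraction_at_or_above_threshold=np.nan,
                    fraction_below_37=np.nan, fraction_above_40=np.nan)
    temps = located["temperature_at_dose"].to_numpy()
    binned = np.array([round_to_tenth(v) for v in temps])
    vals, counts = np.unique(binned, return_counts=True)
    bins = pd.DataFrame({"bin_c": np.round(vals, 1), "count": counts})
    n = len(temps)
    return dict(
        bins=bins,
        n_located=n,
        n_unlocatable=unlocatable,
        fraction_at_or_above_threshold=float(np.mean(temps >= config.fever_threshold)),
        fraction_below_37=float(np.mean(temps < 37.0)),
        fraction_above_40=float(np.mean(temps > 40.0)),
    )


def bin_count(bins: pd.DataFrame, value_c: float) -> int:
    """Count in one 0.1 °C bin (0 if the bin is absent)."""
    m = bins.loc[np.isclose(bins["bin_c"], round(value_c, 1)), "count"]
    return int(m.iloc[0]) if len(m) else 0
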