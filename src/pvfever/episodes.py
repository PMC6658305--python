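"""Filtering cascade and fever-episode extraction.

A vaccination record becomes *analyzable* by surviving, in order:

1. demographics present (age, weight, sex);
2. single vaccination — exactly one shot for that child on that calendar day
   (combination single-shot vaccines such as DTaP or MMR count as single);
3. at least ``min_readings`` temperature readings in the post-vaccination
   window ``(0, window_hours]`` hours;
4. an extractable fever episode: the piecewise-linearly imputed curve both
   reaches the fever threshold and returns below it inside the window;
5. the record's vaccine retains at least ``min_records_per_vaccine``
   surviving records.

Episode definition (threshold 38.0 °C, febrile iff T >= threshold):

* **onset** — first time the imputed curve reaches the threshold, found by
  exact linear inversion of the bracketing segment; if the very first
  in-window reading is already febrile, onset is that reading's time and the
  episode is flagged ``onset_censored``;
* **offset** — last time the curve falls below the threshold (last downward
  crossing); absent when the final reading is still febrile, in which case
  the record yields no episode;
* **duration** = offset − onset (sub-threshold dips between multiple
  crossings are spanned);
* **tmax** — maximum *raw* reading in the window (imputation fills gaps but
  does not manufacture new extrema).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .config import AnalysisConfig, DEFAULT_CONFIG

logger = logging.getLogger(__name__)

CASCADE_STAGES = (
    "input",
    "with_demographics",
    "single_vaccination",
    "min_readings",
    "onset_offset",
    "vaccine_min_records",
)


class PiecewiseLinearCurve:
    """Linear interpolant through readings; exact at every reading.

    Defined only on ``[t_first, t_last]`` — no extrapolation.
    """

    def __init__(self, times: np.ndarray, temps: np.ndarray):
        times = np.asarray(times, dtype=float)
        temps = np.asarray(temps, dtype=float)
        if times.ndim != 1 or times.shape != temps.shape:
            raise ValueError("times and temps must be equal-length 1-d arrays")
        if len(times) < 2:
            raise ValueError("need at least 2 readings to interpolate")
        if np.any(np.diff(times) < 0):
            raise ValueError("times must be sorted")
        if np.any(np.diff(times) == 0):
            raise ValueError("duplicate times must be resolved before interpolation")
        self.times = times
        self.temps = temps

    @property
    def t_min(self) -> float:
        return float(self.times[0])

    @property
    def t_max(self) -> float:
        return float(self.times[-1])

    def __call__(self, t):
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < self.t_min) or np.any(t_arr > self.t_max):
            raise ValueError(
                f"evaluation outside the reading span [{self.t_min}, {self.t_max}]")
        out = np.interp(t_arr, self.times, self.temps)
        return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def impute_linear(times, temps) -> PiecewiseLinearCurve:
    """Piecewise-linear imputation between caregiver readings."""
    return PiecewiseLinearCurve(np.asarray(times, float), np.asarray(temps, float))


@dataclass(frozen=True)
class FeverEpisode:
    """Extracted onset/offset/duration/Tmax for one vaccination record."""

    onset_time_h: float
    offset_time_h: float
    duration_h: float
    tmax_c: float
    onset_censored: bool

    def __post_init__(self) -> None:
        if not (0.0 <= self.onset_time_h <= self.offset_time_h):
            raise ValueError("need 0 <= onset <= offset")
        if abs(self.duration_h - (self.offset_time_h - self.onset_time_h)) > 1e-9:
            raise ValueError("duration must equal offset - onset")


def window_readings(
    times: np.ndarray, temps: np.ndarray, config: AnalysisConfig = DEFAULT_CONFIG
) -> Tuple[np.ndarray, np.ndarray, int]:
    """Restrict readings to ``(0, window_hours]``, sort, and collapse ties.

    Readings sharing a time stamp are collapsed to the maximum temperature
    at that time. Returns ``(times, temps, n_collapsed)``.
    """
    times = np.asarray(times, float)
    temps = np.asarray(temps, float)
    mask = (times > 0.0) & (times <= config.window_hours)
    times, temps = times[mask], temps[mask]
    order = np.argsort(times, kind="stable")
    times, temps = times[order], temps[order]
    uniq, inverse = np.unique(times, return_inverse=True)
    n_collapsed = len(times) - len(uniq)
    if n_collapsed:
        collapsed = np.full(len(uniq), -np.inf)
        np.maximum.at(collapsed, inverse, temps)
        times, temps = uniq, collapsed
        logger.debug("collapsed %d duplicate-time readings (kept max)", n_collapsed)
    return times, temps, n_collapsed


def extract_episode(
    times: np.ndarray, temps: np.ndarray, config: AnalysisConfig = DEFAULT_CONFIG
) -> Optional[FeverEpisode]:
    """Extract the fever episode from windowed, sorted, unique-time readings.

    Returns ``None`` when no reading reaches the threshold or when the final
    reading is still febrile (offset unobserved); absence is a value, not an
    error — such records simply fail the cascade's onset/offset stage.
    """
    times = np.asarray(times, float)
    temps = np.asarray(temps, float)
    if len(times) < 2:
        return None
    thr = config.fever_threshold
    febrile = temps >= thr
    if not febrile.any():
        return None
    if febrile[-1]:
        return None  # fever has not ended inside the window

    first = int(np.argmax(febrile))
    if first == 0:
        onset = float(times[0])
        censored = True
    else:
        t0, t1 = times[first - 1], times[first]
        y0, y1 = temps[first - 1], temps[first]
        onset = float(t0 + (thr - y0) / (y1 - y0) * (t1 - t0))
        censored = False

    last = int(len(times) - 1 - np.argmax(febrile[::-1]))
    t0, t1 = times[last], times[last + 1]
    y0, y1 = temps[last], temps[last + 1]
    # y0 >= thr > y1; crossing of the descending segment
    offset = float(t0) if y0 == thr else float(t0 + (y0 - thr) / (y0 - y1) * (t1 - t0))

    tmax = float(np.max(temps))
    return FeverEpisode(onset, offset, offset - onset, tmax, censored)


def select_single_vaccinations(events: pd.DataFrame) -> pd.DataFrame:
    """Keep vaccination records that are the only one for their child-day.

    Children vaccinated more than once on the same calendar day are excluded
    entirely for that day; a combination vaccine given as one shot (DTaP,
    MMR) is a single vaccination.
    """
    if events.empty:
        return events.copy()
    day = pd.to_datetime(events["time_iso8601"]).dt.normalize()
    counts = events.groupby([events["child_id"], day])["vaccine"].transform("size")
    return events.loc[counts == 1].copy()


def _has_demographics(events: pd.DataFrame) -> pd.Series:
    return (
        events["age_months"].notna()
        & events["weight_kg"].notna()
        & events["sex"].isin(["male", "female"])
    )


def apply_cascade(
    events: pd.DataFrame,
    readings: pd.DataFrame,
    doses: pd.DataFrame,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Run the full filtering cascade and extract episodes.

    Returns ``(records, cascade_counts)``. ``records`` has one row per
    surviving vaccination record with demographics, the antipyretic flag
    (any dose at time in ``[0, window]``), reading count, and the extracted
    episode columns ``onset_h, offset_h, duration_h, tmax_c,
    onset_censored``. ``cascade_counts`` maps each stage to its survivor
    count; counts are monotonically non-increasing.
    """
    counts: Dict[str, int] = {"input": len(events)}

    stage = events.loc[_has_demographics(events)]
    counts["with_demographics"] = len(stage)

    stage = select_single_vaccinations(stage)
    counts["single_vaccination"] = len(stage)

    readings_by_child = {k: v for k, v in readings.groupby("child_id")}
    doses_by_child = {k: v for k, v in doses.groupby("child_id")} if len(doses) else {}

    rows: List[dict] = []
    n_enough = 0
    for ev in stage.itertuples(index=False):
        sub = readings_by_child.get(ev.child_id)
        if sub is None:
            continue
        t, y, _ = window_readings(sub["time_h"].to_numpy(), sub["temp_c"].to_numpy(), config)
        if len(t) < config.min_readings:
            continue
        n_enough += 1
        episode = extract_episode(t, y, config)
        if episode is None:
            continue
        dsub = doses_by_child.get(ev.child_id)
        if dsub is None:
            has_dose = False
        else:
            dt = dsub["time_h"].to_numpy()
            has_dose = bool(np.any((dt >= 0.0) & (dt <= config.window_hours)))
        rows.append(dict(
            child_id=ev.child_id, vaccine=ev.vaccine, time_iso8601=ev.time_iso8601,
            age_months=ev.age_months, weight_kg=ev.weight_kg, sex=ev.sex,
            antipyretic_flag=has_dose, n_readings=len(t),
            onset_h=episode.onset_time_h, offset_h=episode.offset_time_h,
            duration_h=episode.duration_h, tmax_c=episode.tmax_c,
            onset_censored=episode.onset_censored,
        ))
    counts["min_readings"] = n_enough
    counts["onset_offset"] = len(rows)

    records = pd.DataFrame(rows, columns=[
        "child_id", "vaccine", "time_iso8601", "age_months", "weight_kg", "sex",
        "antipyretic_flag", "n_readings", "onset_h", "offset_h", "duration_h",
        "tmax_c", "onset_censored"])
    if len(records):
        per_vaccine = records.groupby("vaccine")["child_id"].transform("size")
        records = records.loc[per_vaccine >= config.min_records_per_vaccine].reset_index(drop=True)
    counts["vaccine_min_records"] = len(records)
    return records, counts


def summarize_cohort(
    records: pd.DataFrame,
    readings: pd.DataFrame,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Per-vaccine cohort characteristics table (plus a Total row).

    Columns mirror the standard baseline-characteristics layout: record and
    child counts, age median/IQR/mean/SD, male count and %, weight stats,
    antipyretic count and %, readings-per-record mean/SD and in-window
    temperature median/IQR/mean/SD. Standard deviations of singletons are
    reported as 0.
    """
    cols = ["vaccine", "n_records", "n_children",
            "age_median", "age_iqr", "age_mean", "age_sd",
            "male_n", "male_pct",
            "weight_median", "weight_iqr", "weight_mean", "weight_sd",
            "antipyretic_n", "antipyretic_pct",
            "readings_mean", "readings_sd",
            "temp_median", "temp_iqr", "temp_mean", "temp_sd"]
    if records.empty:
        return pd.DataFrame(columns=cols)

    in_window = readings.loc[
        (readings["time_h"] > 0) & (readings["time_h"] <= config.window_hours)]
    temp_by_child = {k: v["temp_c"].to_numpy() for k, v in in_window.groupby("child_id")}

    def _sd(x: np.ndarray) -> float:
        return float(np.std(x, ddof=1)) if len(x) > 1 else 0.0

    def _iqr(x: np.ndarray) -> float:
        return float(np.percentile(x, 75) - np.percentile(x, 25))

    def one(name: str, sub: pd.DataFrame) -> dict:
        age = sub["age_months"].to_numpy(float)
        wt = sub["weight_kg"].to_numpy(float)
        nr = sub["n_readings"].to_numpy(float)
        temps = np.concatenate([temp_by_child.get(c, np.empty(0)) for c in sub["child_id"]]) \
            if len(sub) else np.empty(0)
        male = int((sub["sex"] == "male").sum())
        anti = int(sub["antipyretic_flag"].sum())
        return dict(
            vaccine=name, n_records=len(sub), n_children=sub["child_id"].nunique(),
            age_median=float(np.median(age)), age_iqr=_iqr(age),
            age_mean=float(np.mean(age)), age_sd=_sd(age),
            male_n=male, male_pct=100.0 * male / len(sub),
            weight_median=float(np.median(wt)), weight_iqr=_iqr(wt),
            weight_mean=float(np.mean(wt)), weight_sd=_sd(wt),
            antipyretic_n=anti, antipyretic_pct=100.0 * anti / len(sub),
            readings_mean=float(np.mean(nr)), readings_sd=_sd(nr),
            temp_median=float(np.median(temps)) if len(temps) else np.nan,
            temp_iqr=_iqr(temps) if len(temps) else np.nan,
            temp_mean=float(np.mean(temps)) if len(temps) else np.nan,
            temp_sd=_sd(temps) if len(temps) else np.nan,
        )

    rows = [one(v, sub) for v, sub in records.groupby("vaccine", sort=True)]
    rows.append(one("Total", records))
    return pd.DataFrame(rows, columns=cols)
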