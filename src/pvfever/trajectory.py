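"""Onset-aligned temperature trajectories and post-onset decay fits.

Every reading of a record with an extracted episode is mapped to relative
time = reading time − onset, binned into 1 h bins with integer centers over
the configured window (default −3 … +24 h), and summarised per
(vaccine, antipyretic group) as a mean with a t-based 95% confidence
half-width. A straight line fitted through the post-onset bin means
quantifies how fast the group's temperature declines; flatter slopes in the
antipyretic group reflect the transient suppression-and-rebound course of
medicated fevers.

Two binning statistics are available: pooled readings (default) or
per-record imputed values at the bin centers (``per_record_means=True``,
where a record contributes at a center only if its reading span covers it —
no extrapolation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Hashable, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import AnalysisConfig, DEFAULT_CONFIG
from .episodes import impute_linear, window_readings


@dataclass(frozen=True)
class DecayFit:
    """Least-squares line through post-onset trajectory bin means."""

    slope_c_per_h: float
    intercept_c: float
    r_squared: float
    n_bins: int
    degenerate: bool = False


def _bin_centers(config: AnalysisConfig) -> np.ndarray:
    lo, hi = config.trajectory_window
    return np.arange(np.ceil(lo), np.floor(hi) + 1.0)


def _summarise(centers: np.ndarray, rel: np.ndarray, vals: np.ndarray) -> pd.DataFrame:
    """Mean and t-based 95% CI half-width per integer-centered 1 h bin."""
    idx = np.rint(rel).astype(int)
    rows = []
    for c in centers.astype(int):
        v = vals[idx == c]
        n = len(v)
        mean = float(np.mean(v)) if n else np.nan
        if n > 1:
            sd = float(np.std(v, ddof=1))
            half = float(sps.t.ppf(0.975, n - 1) * sd / np.sqrt(n))
        else:
            half = 0.0
        rows.append((c, n, mean, half))
    return pd.DataFrame(rows, columns=["rel_time_h", "n", "mean_c", "ci_half_width_c"])


def align_and_bin(
    records: pd.DataFrame,
    readings: pd.DataFrame,
    config: AnalysisConfig = DEFAULT_CONFIG,
    by_vaccine: bool = True,
    per_record_means: bool = False,
) -> Dict[Hashable, pd.DataFrame]:
    """Onset-aligned binned trajectories per (vaccine, antipyretic) group.

    Returns a dict keyed by ``(vaccine, antipyretic_flag)`` (or just
    ``antipyretic_flag`` when ``by_vaccine=False``) of DataFrames with
    columns ``rel_time_h, n, mean_c, ci_half_width_c``. A reading lands in
    the bin whose integer center is nearest to its relative time. Empty
    groups yield empty series, not errors.
    """
    centers = _bin_centers(config)
    lo, hi = centers[0] - 0.5, centers[-1] + 0.5
    readings_by_child = {k: v for k, v in readings.groupby("child_id")}

    groups: Dict[Hashable, Tuple[list, list]] = {}
    for rec in records.itertuples(index=False):
        sub = readings_by_child.get(rec.child_id)
        if sub is None:
            continue
        t, y, _ = window_readings(sub["time_h"].to_numpy(), sub["temp_c"].to_numpy(), config)
        key = (rec.vaccine, bool(rec.antipyretic_flag)) if by_vaccine else bool(rec.antipyretic_flag)
        rel_list, val_list = groups.setdefault(key, ([], []))
        if per_record_means:
            if len(t) < 2:
                continue
            curve = impute_linear(t, y)
            abs_centers = centers + rec.onset_h
            cover = (abs_centers >= curve.t_min) & (abs_centers <= curve.t_max)
            if cover.any():
                rel_list.extend(centers[cover])
                val_list.extend(np.asarray(curve(abs_centers[cover]), float))
        else:
            rel = t - rec.onset_h
            m = (rel >= lo) & (rel < hi)
            rel_list.extend(rel[m])
            val_list.extend(y[m])

    return {
        key: _summarise(centers, np.asarray(rl, float), np.asarray(vl, float))
        for key, (rl, vl) in groups.items()
    }


def fit_decay(
    series: pd.DataFrame,
    from_h: float = 0.0,
    to_h: float = 24.0,
) -> DecayFit:
    """Ordinary least squares through non-empty bin means in ``[from_h, to_h]``.

    ``R² = 1 − SSE/SST``; when the bin means are constant (SST = 0) the fit
    is degenerate and R² is reported as 0.
    """
    sub = series.loc[
        (series["rel_time_h"] >= from_h)
        & (series["rel_time_h"] <= to_h)
        & (series["n"] > 0)]
    if len(sub) < 3:
        raise ValueError("need >= 3 non-empty bins for a decay fit")
    x = sub["rel_time_h"].to_numpy(float)
    y = sub["mean_c"].to_numpy(float)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        return DecayFit(0.0, float(y.mean()), 0.0, len(sub), degenerate=True)
    slope, intercept = np.polyfit(x, y, 1)
    sse = float(np.sum((y - (slope * x + intercept)) ** 2))
    return DecayFit(float(slope), float(intercept), 1.0 - sse / sst, len(sub))
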