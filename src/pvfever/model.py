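"""Study-level model objects.

:class:`FeverStudy` is built from the three record streams (vaccinations,
temperatures, antipyretic doses); :meth:`FeverStudy.fit` runs the filtering
cascade, episode extraction and the full statistical battery, returning a
:class:`FeverStudyResults` that carries every table and fit and renders a
text ``summary()``.

Typical use::

    study = FeverStudy.from_simulation(n_children=2000, seed=42)
    results = study.fit()
    print(results.summary())
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Hashable, List, Optional

import numpy as np
import pandas as pd

from . import antipyretics as ap
from . import episodes as ep
from . import stats as st
from . import trajectory as tr
from .config import AnalysisConfig, DEFAULT_CONFIG
from .records import load_records
from .simulate import CohortData, generate_cohort

EPISODE_METRICS = ("onset_h", "offset_h", "duration_h", "tmax_c")


class FeverStudy:
    """Postvaccination fever study built from the three record streams."""

    def __init__(
        self,
        vaccinations: pd.DataFrame,
        temperatures: pd.DataFrame,
        doses: pd.DataFrame,
        config: Optional[AnalysisConfig] = None,
    ):
        self.vaccinations = vaccinations
        self.temperatures = temperatures
        self.doses = doses
        self.config = config if config is not None else DEFAULT_CONFIG

    @classmethod
    def from_csv(cls, temperatures_path, vaccinations_path, doses_path,
                 config: Optional[AnalysisConfig] = None) -> "FeverStudy":
        readings, events, doses, _reports = load_records(
            temperatures_path, vaccinations_path, doses_path)
        return cls(events, readings, doses, config)

    @classmethod
    def from_simulation(cls, n_children: int, seed: int = 0,
                        config: Optional[AnalysisConfig] = None,
                        **cohort_kwargs) -> "FeverStudy":
        cohort = generate_cohort(n_children, seed=seed, **cohort_kwargs)
        study = cls(cohort.events, cohort.readings, cohort.doses, config)
        study.ground_truth = cohort.ground_truth
        return study

    def fit(self) -> "FeverStudyResults":
        """Run cascade, extraction and the statistical battery."""
        cfg = self.config
        records, cascade = ep.apply_cascade(
            self.vaccinations, self.temperatures, self.doses, cfg)
        table1 = ep.summarize_cohort(records, self.temperatures, cfg)

        firsts = ap.first_doses(records, self.doses, cfg)
        dose_timing = ap.first_dose_timing(firsts["time_h"].to_numpy(), cfg)
        dose_temps = ap.temperature_at_dose_distribution(
            records, self.temperatures, self.doses, cfg)

        group_tests = self._group_tests(records)
        anova, posthoc = self._vaccine_comparisons(records)
        logistic = self._logistic_fits(records)

        bins = tr.align_and_bin(records, self.temperatures, cfg, by_vaccine=True)
        bins_pooled = tr.align_and_bin(records, self.temperatures, cfg, by_vaccine=False)
        decay = {}
        for key, series in {**bins, **bins_pooled}.items():
            try:
                decay[key] = tr.fit_decay(series, 0.0, cfg.trajectory_window[1])
            except ValueError:
                decay[key] = None

        return FeverStudyResults(
            config=cfg, records=records, cascade_counts=cascade, table1=table1,
            dose_timing=dose_timing, dose_temps=dose_temps,
            group_tests=group_tests, anova=anova, posthoc=posthoc,
            logistic=logistic, trajectory_bins=bins,
            trajectory_bins_pooled=bins_pooled, decay_fits=decay)

    # -- pieces ------------------------------------------------------------

    def _group_tests(self, records: pd.DataFrame) -> pd.DataFrame:
        """Welch tests of each episode metric, antipyretic vs not (overall
        and per vaccine)."""
        rows = []
        scopes = [("All", records)]
        scopes += [(v, sub) for v, sub in records.groupby("vaccine", sort=True)]
        for name, sub in scopes:
            a = sub.loc[sub["antipyretic_flag"]]
            b = sub.loc[~sub["antipyretic_flag"]]
            for metric in EPISODE_METRICS:
                if len(a) < 2 or len(b) < 2:
                    continue
                r = st.welch_t_test(a[metric].to_numpy(), b[metric].to_numpy())
                rows.append(dict(
                    scope=name, metric=metric,
                    mean_antipyretic=r.mean_a, sd_antipyretic=r.sd_a, n_antipyretic=r.n_a,
                    mean_no_antipyretic=r.mean_b, sd_no_antipyretic=r.sd_b,
                    n_no_antipyretic=r.n_b,
                    t_statistic=r.t_statistic, df=r.df, p_value=r.p_value))
        return pd.DataFrame(rows)

    def _vaccine_comparisons(self, records: pd.DataFrame):
        """ANOVA + Levene + Dunnett T3 across vaccines for Tmax and duration."""
        anova: Dict[str, Optional[st.AnovaResult]] = {}
        posthoc: Dict[str, Optional[st.PostHocResult]] = {}
        for metric in ("tmax_c", "duration_h"):
            groups = {v: sub[metric].to_numpy()
                      for v, sub in records.groupby("vaccine", sort=True)
                      if len(sub) >= 2}
            if len(groups) < 2:
                anova[metric] = None
                posthoc[metric] = None
                continue
            anova[metric] = st.oneway_anova_with_levene(groups)
            posthoc[metric] = (st.dunnett_t3(groups, alpha=self.config.alpha)
                               if len(groups) >= 3 else None)
        return anova, posthoc

    def _logistic_fits(self, records: pd.DataFrame) -> Dict[str, Optional[st.LogisticFit]]:
        """High-fever logistic model per vaccine and for all records."""
        cfg = self.config
        out: Dict[str, Optional[st.LogisticFit]] = {}
        scopes = [(v, sub) for v, sub in records.groupby("vaccine", sort=True)]
        scopes.append(("All", records))
        for name, sub in scopes:
            data = sub[["age_months", "weight_kg", "sex"]].copy()
            data["high_fever"] = (sub["tmax_c"] >= cfg.high_fever_threshold).astype(int)
            try:
                out[name] = st.fit_high_fever_logistic(
                    data, vif_limit=cfg.vif_limit)
            except (ValueError, st.SeparationError, st.ConvergenceError):
                out[name] = None
        return out


@dataclass
class FeverStudyResults:
    """Results container: cascade, tables, tests, trajectories.

    Attributes mirror the analysis battery: ``cascade_counts`` (survivors per
    filtering stage), ``table1`` (cohort characteristics), ``dose_timing`` /
    ``dose_temps`` (antipyretic patterns), ``group_tests`` (Welch contrasts),
    ``anova`` / ``posthoc`` (across-vaccine comparisons of Tmax and
    duration), ``logistic`` (high-fever models with VIFs), and
    ``trajectory_bins`` / ``decay_fits`` (onset-aligned courses).
    """

    config: AnalysisConfig
    records: pd.DataFrame
    cascade_counts: Dict[str, int]
    table1: pd.DataFrame
    dose_timing: pd.DataFrame
    dose_temps: Dict[str, object]
    group_tests: pd.DataFrame
    anova: Dict[str, Optional[st.AnovaResult]]
    posthoc: Dict[str, Optional[st.PostHocResult]]
    logistic: Dict[str, Optional[st.LogisticFit]]
    trajectory_bins: Dict[Hashable, pd.DataFrame]
    trajectory_bins_pooled: Dict[Hashable, pd.DataFrame]
    decay_fits: Dict[Hashable, Optional[tr.DecayFit]]

    @property
    def episodes(self) -> pd.DataFrame:
        """Extracted episodes (one row per surviving vaccination record)."""
        return self.records[["child_id", "vaccine", "onset_h", "offset_h",
                             "duration_h", "tmax_c", "onset_censored",
                             "antipyretic_flag"]]

    def summary(self) -> str:
        """Readable multi-section text summary of the whole analysis."""
        lines: List[str] = []
        w = lines.append
        w("Postvaccination fever study")
        w("=" * 64)
        w("Filtering cascade (records surviving each stage):")
        for k in ep.CASCADE_STAGES:
            if k in self.cascade_counts:
                w(f"  {k:>22}: {self.cascade_counts[k]}")
        w("")
        w("Cohort characteristics by vaccine:")
        if self.table1.empty:
            w("  (no analyzable records)")
        else:
            cols = ["vaccine", "n_records", "age_mean", "male_pct",
                    "weight_mean", "antipyretic_pct", "readings_mean", "temp_mean"]
            w(self.table1[cols].to_string(index=False, float_format=lambda v: f"{v:.2f}"))
        w("")
        if len(self.dose_timing) and self.dose_timing["count"].sum():
            cum10 = float(self.dose_timing.loc[self.dose_timing["hour"] == 10,
                                               "cumulative_fraction"].iloc[0])
            w("Antipyretic pattern: "
              f"{100 * self.dose_timing['fraction'].iloc[0]:.2f}% of first doses "
              f"within 1 h; cumulative {100 * cum10:.2f}% by 10 h; "
              f"{100 * self.dose_temps['fraction_at_or_above_threshold']:.2f}% of "
              "located first doses at >= 38.0 C")
            w("")
        for metric, label in (("tmax_c", "Maximum temperature (C)"),
                              ("duration_h", "Fever duration (h)")):
            a = self.anova.get(metric)
            if a is None:
                continue
            w(f"{label}: F({a.df_between},{a.df_within}) = {a.f_statistic:.1f}, "
              f"p = {a.p_value:.3g}; Levene p = {a.levene_p:.3g}")
            ph = self.posthoc.get(metric)
            if ph is not None:
                order = " > ".join("{" + ", ".join(b) + "}" for b in ph.partition)
                w(f"  Dunnett T3 grouping: {order}")
        w("")
        for name, fit in self.logistic.items():
            if fit is None:
                continue
            w(f"High-fever logistic model [{name}] (n={fit.n}, events={fit.n_events}):")
            sub = fit.table.loc[fit.table["term"] != "const"]
            for r in sub.itertuples(index=False):
                w(f"  {r.term:>10}: B = {r.coef:.3f} (SE {r.se:.3f}), p = {r.p_value:.3g}, "
                  f"OR = {r.odds_ratio:.3f} ({r.ci_low:.3f}-{r.ci_high:.3f})")
            vifs = ", ".join(f"{r.predictor} {r.vif:.2f}"
                             for r in fit.vif.table.itertuples(index=False))
            w(f"  VIF: {vifs}")
        w("")
        pooled = {k: v for k, v in self.decay_fits.items() if isinstance(k, bool)}
        if pooled:
            w("Post-onset decay (pooled across vaccines):")
            for flag in (False, True):
                d = pooled.get(flag)
                if d is not None:
                    grp = "antipyretic" if flag else "no antipyretic"
                    w(f"  {grp:>15}: slope {d.slope_c_per_h:+.3f} C/h, R2 = {d.r_squared:.2f}")
        return "\n".join(lines)

    # -- plotting ----------------------------------------------------------

    def plot_trajectories(self, by_vaccine: bool = True, ax=None):
        """Onset-aligned mean temperature with 95% CI bands per group."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 5))
        source = self.trajectory_bins if by_vaccine else self.trajectory_bins_pooled
        for key, series in sorted(source.items(), key=str):
            sub = series.loc[series["n"] > 0]
            if by_vaccine:
                vac, flag = key
                label = f"{vac} ({'antipyretic' if flag else 'none'})"
            else:
                label = "antipyretic" if key else "no antipyretic"
            ax.plot(sub["rel_time_h"], sub["mean_c"], marker="o", ms=3, label=label)
            ax.fill_between(sub["rel_time_h"],
                            sub["mean_c"] - sub["ci_half_width_c"],
                            sub["mean_c"] + sub["ci_half_width_c"], alpha=0.15)
        ax.axhline(self.config.fever_threshold, color="grey", ls="--", lw=0.8)
        ax.set_xlabel("hours from fever onset")
        ax.set_ylabel("body temperature (C)")
        ax.legend(fontsize=7)
        return ax

    def plot_dose_temperatures(self, ax=None):
        """Histogram of body temperature at first antipyretic dose."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        bins = self.dose_temps["bins"]
        ax.bar(bins["bin_c"], bins["count"], width=0.09)
        ax.axvline(self.config.fever_threshold, color="red", ls="--", lw=0.8)
        ax.set_xlabel("temperature at first dose (C)")
        ax.set_ylabel("doses")
        return ax
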