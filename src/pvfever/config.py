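"""Analysis configuration: every threshold and window used by the pipeline.

All quantities that gate the filtering cascade, the episode definition and the
statistical battery live here so that a run is fully described by one object.
Times are real-valued hours relative to the anchoring vaccination (vaccination
instant = 0 h); temperatures are degrees Celsius.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Tuple


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds and windows for fever-episode extraction and analysis.

    Parameters
    ----------
    fever_threshold : float
        Body temperature defining fever, °C. A reading is febrile iff
        temperature >= fever_threshold.
    high_fever_threshold : float
        Outcome threshold for the "relatively high fever" logistic model, °C.
    window_hours : float
        Post-vaccination observation window; readings at time in
        ``(0, window_hours]`` hours are analyzable.
    min_readings : int
        Minimum number of in-window temperature readings for a vaccination
        record to be analyzable.
    min_records_per_vaccine : int
        Vaccines with fewer surviving records than this are excluded from the
        comparative analyses.
    trajectory_window : tuple of float
        Hours relative to fever onset over which onset-aligned trajectories
        are binned (negative = before onset).
    vif_limit : float
        Variance-inflation-factor value above which predictors are flagged as
        collinear.
    alpha : float
        Two-sided significance level for every test in the battery.
    """

    fever_threshold: float = 38.0
    high_fever_threshold: float = 39.0
    window_hours: float = 48.0
    min_readings: int = 5
    min_records_per_vaccine: int = 100
    trajectory_window: Tuple[float, float] = (-3.0, 24.0)
    vif_limit: float = 10.0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not self.fever_threshold < self.high_fever_threshold:
            raise ValueError("fever_threshold must be < high_fever_threshold")
        if not self.window_hours > 0:
            raise ValueError("window_hours must be positive")
        if self.min_readings < 2:
            raise ValueError("min_readings must be >= 2")
        lo, hi = self.trajectory_window
        if not (lo < 0 < hi):
            raise ValueError("trajectory_window must straddle onset: lo < 0 < hi")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.vif_limit <= 1:
            raise ValueError("vif_limit must exceed 1")
        if self.min_records_per_vaccine < 1:
            raise ValueError("min_records_per_vaccine must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["trajectory_window"] = list(self.trajectory_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        if "trajectory_window" in d:
            d["trajectory_window"] = tuple(d["trajectory_window"])
        return cls(**d)


DEFAULT_CONFIG = AnalysisConfig()
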