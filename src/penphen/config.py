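"""Configuration objects for simulation and quality control.

Default trait means, SDs and heritable fractions are calibrated to
published summary statistics for camera-derived behavior of purebred
finisher pigs recorded 14 h/day over a 70-day test (times in minutes per
day, distance in meters per day) and their off-test production traits
(ADG g/day, back fat mm, loin depth mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from datetime import date

import numpy as np
import yaml

BEHAVIOR_TRAITS = ["eating", "drinking", "lateral", "sternal", "sitting",
                   "standing", "distance"]
PRODUCTION_TRAITS = ["adg", "bf", "ld"]
POSTURE_TRAITS = ["lateral", "sternal", "sitting", "standing"]

#: record-table column for each behavior trait
RECORD_COLUMNS = {
    "eating": "eating_min", "drinking": "drinking_min", "lateral": "lateral_min",
    "sternal": "sternal_min", "sitting": "sitting_min", "standing": "standing_min",
    "distance": "distance_m",
}

DAY_RECORD_HEADER = [
    "animal_id", "group_id", "date", "day_index", "recording_minutes",
    "eating_min", "drinking_min", "lateral_min", "sternal_min", "sitting_min",
    "standing_min", "distance_m", "culled_today",
]

# population-level daily means and SDs (finisher gilts, 14-h recording day)
DEFAULT_MEANS = {
    "eating": 56.41, "drinking": 7.25, "lateral": 287.52, "sternal": 359.12,
    "sitting": 22.97, "standing": 170.28, "distance": 872.55,
    "adg": 710.59, "bf": 8.33, "ld": 66.34,
}
DEFAULT_SDS = {
    "eating": 19.55, "drinking": 4.51, "lateral": 90.81, "sternal": 73.59,
    "sitting": 18.13, "standing": 52.21, "distance": 357.47,
    "adg": 63.98, "bf": 2.30, "ld": 5.40,
}
# additive fractions of phenotypic variance used as simulation defaults
DEFAULT_H2 = {
    "eating": 0.57, "drinking": 0.38, "lateral": 0.19, "sternal": 0.22,
    "sitting": 0.48, "standing": 0.43, "distance": 0.38,
    "adg": 0.38, "bf": 0.53, "ld": 0.30,
}
# qualitative age trends: eating/standing/distance fall, lying rises,
# drinking flat (linear, quadratic) coefficients per day on test, centred
# at mid-test so trends do not move the grand mean.
DEFAULT_TRENDS = {
    "eating": (-0.30, 0.0), "drinking": (0.0, 0.0), "lateral": (0.50, 0.0),
    "sternal": (0.30, 0.0), "sitting": (-0.05, 0.0), "standing": (-0.50, 0.0),
    "distance": (-3.0, 0.0),
}


class ConfigError(ValueError):
    """Invalid simulation or QC configuration."""


def _check_psd(M: np.ndarray, name: str, tol: float = 1e-8) -> None:
    M = np.asarray(M, dtype=float)
    if M.shape[0] != M.shape[1]:
        raise ConfigError(f"{name} must be square")
    if not np.allclose(M, M.T, atol=1e-10):
        raise ConfigError(f"{name} must be symmetric")
    w = np.linalg.eigvalsh(M)
    if w.min() < -tol * max(1.0, abs(w).max()):
        raise ConfigError(f"{name} is not positive semi-definite (min eig {w.min():g})")


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic-data generator."""

    n_founders: int = 200
    n_generations: int = 2
    litter_size_mean: float = 8.0
    n_litters_per_gen: int = 50
    n_lines: int = 2
    traits: list = field(default_factory=lambda: list(BEHAVIOR_TRAITS))
    G_true: np.ndarray | None = None      # additive (co)variance, trait units^2
    L_true: np.ndarray | None = None      # common-litter (co)variance
    C_true: np.ndarray | None = None      # contemporary-group (co)variance
    R_true: np.ndarray | None = None      # animal-level residual (co)variance
    line_means: np.ndarray | None = None  # (n_lines, n_traits)
    n_test_days: int = 70
    daily_hours: float = 14.0
    trend: dict = field(default_factory=dict)  # trait -> (linear, quadratic)
    p_short_day: float = 0.0
    short_day_hours_range: tuple = (4.0, 13.0)
    p_cull: float = 0.0
    p_distance_artifact: float = 0.0
    max_distance_rate: float = 15.0           # m per standing-min, physical bound
    day_noise_sd: np.ndarray | None = None    # per-trait within-animal day SD
    day_noise_ar1: float = 0.0                # AR(1) coefficient of day noise
    group_size: int = 19                       # pigs per camera/recording group
    n_contemp_groups: int = 20                 # distinct off-test day-year batches
    learning_groups: int = 0                   # early groups tagged as learning data
    record_founders: bool = False
    start_date: date = date(2022, 1, 3)
    seed: int = 0
    mode: str = "animal_level"                 # or "day_level"

    def __post_init__(self):
        if self.n_founders < 2 * self.n_lines:
            raise ConfigError("need at least 2 founders per line")
        if min(self.n_founders, self.n_lines, self.litter_size_mean) <= 0:
            raise ConfigError("counts must be positive")
        if self.n_generations < 0 or self.n_litters_per_gen <= 0:
            raise ConfigError("counts must be positive")
        if self.n_test_days < 3:
            raise ConfigError("n_test_days must be >= 3")
        for p in (self.p_short_day, self.p_cull, self.p_distance_artifact):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("probabilities must lie in [0, 1]")
        if not -1.0 < self.day_noise_ar1 < 1.0:
            raise ConfigError("day_noise_ar1 must lie in (-1, 1)")
        if self.mode not in ("animal_level", "day_level"):
            raise ConfigError(f"unknown mode {self.mode!r}")

        k = len(self.traits)
        for name in ("G_true", "L_true", "C_true", "R_true"):
            M = getattr(self, name)
            if M is not None:
                _check_psd(np.asarray(M, dtype=float), name)
        sds = np.array([DEFAULT_SDS.get(t, 1.0) for t in self.traits])
        h2 = np.array([DEFAULT_H2.get(t, 0.3) for t in self.traits])
        # day-level SDs include within-animal day-to-day noise; by default
        # 40% of the daily variance is day noise and 60% animal level.
        w_day = 0.4 if self.mode == "day_level" else 0.0
        v_animal = (1.0 - w_day) * sds**2
        if self.G_true is None:
            self.G_true = np.diag(h2 * v_animal)
        if self.L_true is None:
            self.L_true = np.diag(0.05 * v_animal)
        if self.C_true is None:
            self.C_true = np.diag(0.05 * v_animal)
        if self.R_true is None:
            resid = v_animal - np.diag(self.G_true) - np.diag(self.L_true) \
                - np.diag(self.C_true)
            if np.any(resid < 0):
                raise ConfigError("implied residual variance is negative")
            self.R_true = np.diag(resid)
        if self.day_noise_sd is None:
            self.day_noise_sd = np.sqrt(w_day) * sds
        self.day_noise_sd = np.asarray(self.day_noise_sd, dtype=float) * np.ones(k)
        if self.line_means is None:
            mu = np.array([DEFAULT_MEANS.get(t, 0.0) for t in self.traits])
            offs = np.linspace(-0.1, 0.1, self.n_lines)[:, None]
            self.line_means = mu[None, :] + offs * sds[None, :]
        self.line_means = np.atleast_2d(np.asarray(self.line_means, dtype=float))
        if self.line_means.shape != (self.n_lines, k):
            raise ConfigError("line_means must be (n_lines, n_traits)")
        if not self.trend:
            self.trend = {t: DEFAULT_TRENDS.get(t, (0.0, 0.0)) for t in self.traits}
        for name in ("G_true", "L_true", "C_true", "R_true"):
            M = np.asarray(getattr(self, name), dtype=float)
            if M.shape != (k, k):
                raise ConfigError(f"{name} must be {k}x{k}")
            _check_psd(M, name)
            setattr(self, name, M)

    @property
    def day_traits(self) -> list:
        return [t for t in self.traits if t in BEHAVIOR_TRAITS]

    @property
    def production_traits(self) -> list:
        return [t for t in self.traits if t in PRODUCTION_TRAITS]

    # -- YAML round trip ---------------------------------------------------
    def to_yaml(self, path) -> None:
        d = asdict(self)
        for key in ("G_true", "L_true", "C_true", "R_true", "line_means",
                    "day_noise_sd"):
            d[key] = np.asarray(d[key]).tolist()
        d["start_date"] = self.start_date.isoformat()
        d["short_day_hours_range"] = list(self.short_day_hours_range)
        d["trend"] = {t: list(v) for t, v in self.trend.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("G_true", "L_true", "C_true", "R_true", "line_means",
                    "day_noise_sd"):
            if d.get(key) is not None:
                d[key] = np.asarray(d[key], dtype=float)
        d["start_date"] = date.fromisoformat(d["start_date"])
        d["short_day_hours_range"] = tuple(d["short_day_hours_range"])
        d["trend"] = {t: tuple(v) for t, v in d.get("trend", {}).items()}
        return cls(**d)


@dataclass
class QCConfig:
    """Parameters of the day-record cleaning rules."""

    learning_period_end: date | str | None = None
    learning_group_tags: frozenset | None = None
    min_hours: float = 8.0
    full_day_hours: float = 14.0
    max_distance_per_standing_min: float = 15.0
    drop_boundary_days: bool = True
    n_test_days: int | None = 70          # nominal recording-group length
    distance_mode: str = "discard"        # or "cap"

    def __post_init__(self):
        if not 0 < self.min_hours <= self.full_day_hours:
            raise ConfigError("need 0 < min_hours <= full_day_hours")
        if self.max_distance_per_standing_min <= 0:
            raise ConfigError("max distance rate must be positive")
        if self.distance_mode not in ("discard", "cap"):
            raise ConfigError(f"unknown distance_mode {self.distance_mode!r}")
        if isinstance(self.learning_period_end, str):
            self.learning_period_end = date.fromisoformat(self.learning_period_end)
        if self.learning_group_tags is not None:
            self.learning_group_tags = frozenset(self.learning_group_tags)

    @property
    def min_minutes(self) -> float:
        return self.min_hours * 60.0

    @property
    def full_day_minutes(self) -> float:
        return self.full_day_hours * 60.0

    @classmethod
    def from_yaml(cls, path) -> "QCConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "learning_group_tags" in d and d["learning_group_tags"] is not None:
            d["learning_group_tags"] = frozenset(d["learning_group_tags"])
        return cls(**d)
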