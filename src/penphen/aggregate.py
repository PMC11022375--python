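"""Per-animal phenotypes from cleaned day records.

Behavior phenotypes are unweighted per-animal means over surviving days,
either over the whole test or over five sub-intervals of the day-on-test
index (defaults: 1-13, 14-26, 27-40, 41-54, 55-68, chosen so the removed
boundary days 1 and 70 never contribute).  Day x day and week x week
phenotypic correlation matrices quantify redundancy of recording time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import BEHAVIOR_TRAITS, RECORD_COLUMNS

log = logging.getLogger(__name__)

DEFAULT_INTERVALS = [(1, 13), (14, 26), (27, 40), (41, 54), (55, 68)]


@dataclass(frozen=True)
class IntervalSet:
    """Ordered, non-overlapping inclusive (start_day, end_day) pairs."""

    intervals: tuple = tuple(DEFAULT_INTERVALS)

    def __post_init__(self):
        prev_end = 0
        for s, e in self.intervals:
            if not (0 < s <= e):
                raise ValueError(f"bad interval ({s}, {e})")
            if s <= prev_end:
                raise ValueError("intervals overlap or are out of order")
            prev_end = e

    def label(self, i: int) -> str:
        s, e = self.intervals[i]
        return f"d{s:02d}-{e:02d}"

    def __iter__(self):
        return iter(self.intervals)

    def __len__(self):
        return len(self.intervals)


def _merge_covariates(means: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    keys = [c for c in ("line", "litter", "cg") if c in covariates.columns]
    out = means.merge(covariates[["animal_id", *keys]], on="animal_id", how="left")
    bad = out[keys].isna().any(axis=1)
    if bad.any():
        log.warning("excluding %d animals with missing line/litter/cg", bad.sum())
        out = out.loc[~bad]
    return out.reset_index(drop=True)


def average_full_period(records: pd.DataFrame, covariates: pd.DataFrame,
                        min_days: int = 10,
                        traits: list | None = None) -> pd.DataFrame:
    """Per-animal mean of each trait over all surviving days.

    Traits observed on fewer than `min_days` days for an animal are set
    missing for that animal; `n_days_<trait>` columns report the counts.
    """
    traits = traits or [t for t in BEHAVIOR_TRAITS
                        if RECORD_COLUMNS[t] in records.columns]
    cols = {t: RECORD_COLUMNS[t] for t in traits}
    g = records.groupby("animal_id")
    means = g[list(cols.values())].mean()
    counts = g[list(cols.values())].count()
    for t, c in cols.items():
        means.loc[counts[c] < min_days, c] = np.nan
    means = means.rename(columns={c: t for t, c in cols.items()})
    for t, c in cols.items():
        means[f"n_days_{t}"] = counts[c]
    means = means.reset_index()
    return _merge_covariates(means, covariates)


def average_intervals(records: pd.DataFrame, covariates: pd.DataFrame,
                      intervals: IntervalSet | None = None, min_days: int = 1,
                      traits: list | None = None) -> dict:
    """Full-period averaging restricted to each day-on-test interval.

    Returns {interval label: PhenotypeTable}.  Records outside every
    interval (e.g. days 69-70 under the defaults) contribute to none.
    """
    intervals = intervals or IntervalSet()
    out = {}
    for i, (s, e) in enumerate(intervals):
        sub = records.loc[(records["day_index"] >= s) & (records["day_index"] <= e)]
        out[intervals.label(i)] = average_full_period(
            sub, covariates, min_days=min_days, traits=traits)
    return out


def day_week_correlations(records: pd.DataFrame, trait: str):
    """Across-animal Pearson correlations between days and between weeks.

    Pairwise-complete observations; any cell with fewer than 3 complete
    pairs (or zero variance) is missing.  Week k covers day indices
    7(k-1)+1 .. 7k.  Returns (day_corr, week_corr) DataFrames with unit
    diagonals where defined.
    """
    col = RECORD_COLUMNS.get(trait, trait)
    wide = records.pivot_table(index="animal_id", columns="day_index",
                               values=col, aggfunc="mean")
    if wide.shape[0] < 2:
        raise ValueError("need at least 2 animals with overlapping days")
    day_corr = wide.corr(min_periods=3)
    week_of = (wide.columns.to_numpy(dtype=int) - 1) // 7 + 1
    weekly = wide.T.groupby(week_of).mean().T
    weekly.columns.name = "week"
    week_corr = weekly.corr(min_periods=3)
    return day_corr, week_corr
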