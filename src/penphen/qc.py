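"""Rule-based cleaning of day-wise behavior records.

Four rules, applied in a fixed order with a per-rule audit trail:

1. drop learning-period data (early recording groups, by date or group tag);
2. drop days with under 8 h of recording; rescale 8-14 h days up to the
   full 14-h equivalent (all six behavior times and the distance scale by
   the same factor, so posture-sum closure and the distance/standing ratio
   are preserved);
3. drop cull-day records (extraction time within the day is unknown) and
   the first and last nominal day of every recording group;
4. drop records whose distance exceeds 15 m per minute of standing — a
   known artifact of distance accumulating while a pig rotates sitting.

Rule counts depend on this order; the pipeline order is fixed and the
whole procedure is idempotent.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from datetime import date

import numpy as np
import pandas as pd

from .config import QCConfig, RECORD_COLUMNS

log = logging.getLogger(__name__)

BEHAVIOR_VALUE_COLS = list(RECORD_COLUMNS.values())


class QCError(ValueError):
    """Records table is missing information a rule needs."""


@dataclass
class QCReport:
    """Per-rule audit: record/animal counts in, out, and removed by rule."""

    records_in: int = 0
    records_out: int = 0
    animals_in: int = 0
    animals_out: int = 0
    removed: dict = field(default_factory=dict)   # rule -> records removed
    rescaled: int = 0                             # 8-14 h records scaled up
    animals_removed: dict = field(default_factory=dict)  # rule -> animals lost

    def check(self) -> None:
        total = sum(self.removed.values())
        if self.records_in != self.records_out + total:
            raise QCError("QC report does not reconcile: "
                          f"{self.records_in} != {self.records_out} + {total}")

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def _n_animals(df: pd.DataFrame) -> int:
    return int(df["animal_id"].nunique())


def remove_learning_period(records: pd.DataFrame, cfg: QCConfig):
    """Drop records from the equipment/algorithm learning period."""
    if cfg.learning_group_tags is not None:
        keep = ~records["group_id"].isin(cfg.learning_group_tags)
    elif cfg.learning_period_end is not None:
        if "date" not in records.columns:
            raise QCError("records carry no date column for the learning cutoff")
        dates = pd.to_datetime(records["date"]).dt.date
        keep = dates >= cfg.learning_period_end
    else:
        return records, 0
    out = records.loc[keep]
    return out, int((~keep).sum())


def filter_and_rescale_hours(records: pd.DataFrame, cfg: QCConfig):
    """Remove sub-8-h days; scale 8-14 h days up to the 14-h equivalent.

    Returns (records, removed_short, removed_invalid, n_rescaled).  Records
    claiming more recording time than the nominal day are invalid and are
    removed and counted separately.
    """
    m = records["recording_minutes"].to_numpy(dtype=float)
    full = cfg.full_day_minutes
    invalid = m > full + 1e-9
    short = (m < cfg.min_minutes) & ~invalid
    partial = ~invalid & ~short & (m < full - 1e-9)
    out = records.loc[~(short | invalid)].copy()
    pm = partial[~(short | invalid)]
    if pm.any():
        factor = full / out.loc[pm, "recording_minutes"].to_numpy(dtype=float)
        cols = [c for c in BEHAVIOR_VALUE_COLS if c in out.columns]
        out.loc[pm, cols] = out.loc[pm, cols].to_numpy(dtype=float) * factor[:, None]
        out.loc[pm, "recording_minutes"] = full
    return out, int(short.sum()), int(invalid.sum()), int(pm.sum())


def remove_nonrepresentative_days(records: pd.DataFrame, cfg: QCConfig):
    """Drop cull-day records and each group's first/last nominal test day."""
    if "culled_today" not in records.columns:
        raise QCError("records carry no culled_today flag")
    cull = records["culled_today"].astype(bool).to_numpy()
    n_cull = int(cull.sum())
    out = records.loc[~cull]
    n_bound = 0
    if cfg.drop_boundary_days:
        if cfg.n_test_days is None:
            raise QCError("recording-group length unknown: set QCConfig.n_test_days")
        di = out["day_index"].to_numpy()
        boundary = (di == 1) | (di == cfg.n_test_days)
        n_bound = int(boundary.sum())
        out = out.loc[~boundary]
    return out, n_cull, n_bound


def filter_distance_ratio(records: pd.DataFrame, cfg: QCConfig):
    """Discard records whose distance exceeds `max_rate` x standing minutes.

    The bound is strict ("exceeded"): distance == rate * standing survives.
    Standing 0 with positive distance is impossible and is removed; standing
    0 with distance 0 survives.  `distance_mode="cap"` truncates instead of
    discarding.
    """
    dist = records["distance_m"].to_numpy(dtype=float)
    stand = records["standing_min"].to_numpy(dtype=float)
    limit = cfg.max_distance_per_standing_min * stand
    bad = dist > limit + 1e-12
    if cfg.distance_mode == "cap":
        out = records.copy()
        out.loc[bad, "distance_m"] = limit[bad]
        return out, 0
    return records.loc[~bad], int(bad.sum())


def run_qc(records: pd.DataFrame, cfg: QCConfig):
    """Apply all rules in the fixed pipeline order; return (clean, QCReport)."""
    report = QCReport(records_in=len(records), animals_in=_n_animals(records))

    def note(rule, before, after):
        report.animals_removed[rule] = before - after

    cur = records
    a0 = _n_animals(cur)
    cur, n = remove_learning_period(cur, cfg)
    report.removed["learning_period"] = n
    note("learning_period", a0, a1 := _n_animals(cur))
    log.info("QC learning_period: removed %d records", n)

    cur, n_short, n_invalid, n_scaled = filter_and_rescale_hours(cur, cfg)
    report.removed["short_day"] = n_short
    report.removed["invalid_duration"] = n_invalid
    report.rescaled = n_scaled
    note("hours", a1, a2 := _n_animals(cur))
    log.info("QC hours: removed %d short, %d invalid; rescaled %d",
             n_short, n_invalid, n_scaled)

    cur, n_cull, n_bound = remove_nonrepresentative_days(cur, cfg)
    report.removed["cull_day"] = n_cull
    report.removed["boundary_day"] = n_bound
    note("nonrepresentative", a2, a3 := _n_animals(cur))
    log.info("QC nonrepresentative: removed %d cull-day, %d boundary-day",
             n_cull, n_bound)

    cur, n_ratio = filter_distance_ratio(cur, cfg)
    report.removed["distance_ratio"] = n_ratio
    note("distance_ratio", a3, _n_animals(cur))
    log.info("QC distance_ratio: removed %d records", n_ratio)

    report.records_out = len(cur)
    report.animals_out = _n_animals(cur)
    report.check()
    return cur.reset_index(drop=True), report
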