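"""Synthetic pig behavior data with known genetic ground truth.

Emulates a video-phenotyping study: a two-line purebred pedigree, additive
breeding values propagated by Mendelian sampling, common-litter and
contemporary-group effects, and day-wise behavior records over a 70-day
test at 14 h of recording per day — including the data defects a cleaning
pipeline must catch (short recording days, cull days, sitting-rotation
distance artifacts, a learning period of early recording groups).

Two modes:

* ``animal_level`` — one phenotype per animal per trait, drawn exactly from
  the model ``y = line + u + l + c + e``.  The target for variance-component
  recovery, since day averaging changes the effective residual.
* ``day_level`` — a full day-wise record table with age trends, AR(1) day
  noise, posture-sum closure and injected defects, for QC and aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import timedelta

import numpy as np
import pandas as pd

from .config import (BEHAVIOR_TRAITS, DAY_RECORD_HEADER, POSTURE_TRAITS,
                     RECORD_COLUMNS, ConfigError, SimConfig)
from .pedigree import Pedigree, inbreeding

# independent RNG streams per generation stage
_STAGES = {"pedigree": 11, "groups": 13, "effects": 17, "days": 19,
           "production": 23}


def _rng(cfg: SimConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed), _STAGES[stage]])


@dataclass
class SimPedigree:
    """Pedigree plus per-animal structure (line, generation, litter, sex)."""

    pedigree: Pedigree
    meta: pd.DataFrame  # animal_id, line, generation, litter, sex


def simulate_pedigree(cfg: SimConfig) -> SimPedigree:
    """Two-line pedigree: founders plus `n_generations` of litters.

    Each litter has one sire-dam pair from the previous generation of the
    same line; litter sizes are Poisson around `litter_size_mean`,
    truncated at 1.  Output order is generation order, so parents always
    precede offspring.
    """
    rng = _rng(cfg, "pedigree")
    rows = []  # (animal, sire, dam, line, gen, litter, sex)
    next_id = 1
    per_line = cfg.n_founders // cfg.n_lines
    by_line_gen: dict = {}
    for line in range(cfg.n_lines):
        members = []
        for j in range(per_line):
            sex = "M" if j < per_line // 2 else "F"
            rows.append((next_id, 0, 0, line, 0, -1, sex))
            members.append((next_id, sex))
            next_id += 1
        by_line_gen[(line, 0)] = members

    litter_id = 0
    litters_per_line = max(1, cfg.n_litters_per_gen // cfg.n_lines)
    for gen in range(1, cfg.n_generations + 1):
        for line in range(cfg.n_lines):
            prev = by_line_gen[(line, gen - 1)]
            males = [a for a, s in prev if s == "M"]
            females = [a for a, s in prev if s == "F"]
            if not males or not females:
                raise ConfigError("a line ran out of sires or dams")
            n_lit = litters_per_line
            dams = rng.choice(females, size=n_lit, replace=n_lit > len(females))
            members = []
            for d in dams:
                s = int(rng.choice(males))
                size = max(1, int(rng.poisson(cfg.litter_size_mean)))
                for j in range(size):
                    sex = "M" if rng.random() < 0.5 else "F"
                    rows.append((next_id, s, int(d), line, gen, litter_id, sex))
                    members.append((next_id, sex))
                    next_id += 1
                litter_id += 1
            by_line_gen[(line, gen)] = members

    ped = Pedigree.from_triples([(a, s, d) for a, s, d, *_ in rows])
    meta = pd.DataFrame(rows, columns=["animal_id", "sire", "dam", "line",
                                       "generation", "litter", "sex"])
    meta = meta.drop(columns=["sire", "dam"])
    return SimPedigree(pedigree=ped, meta=meta)


def assign_groups(meta: pd.DataFrame, cfg: SimConfig) -> pd.DataFrame:
    """Attach recording groups and contemporary groups to the meta table.

    Recorded animals (non-founders unless `record_founders`) are chunked
    into camera/recording groups of `group_size`; consecutive recording
    groups share an off-test batch, giving `n_contemp_groups` contemporary
    groups (off-test day-year), mirroring how off-test dates align with
    recording groups in practice.
    """
    meta = meta.copy()
    recorded = (meta["generation"] > 0) | cfg.record_founders
    meta["recorded"] = recorded
    idx = meta.index[recorded]
    n_rec = len(idx)
    n_groups = max(1, int(np.ceil(n_rec / cfg.group_size)))
    group = np.repeat(np.arange(n_groups), cfg.group_size)[:n_rec]
    meta["recording_group"] = -1
    meta.loc[idx, "recording_group"] = group
    n_cg = min(cfg.n_contemp_groups, n_groups)
    meta["cg"] = -1
    meta.loc[idx, "cg"] = (group * n_cg) // n_groups
    return meta


@dataclass
class TrueEffects:
    """Per-animal true model effects for every trait (sidecar ground truth)."""

    meta: pd.DataFrame          # includes recording_group, cg, recorded
    traits: list
    u: np.ndarray               # (n_animals, n_traits) breeding values
    l: np.ndarray               # litter effects (0 for animals without litter)
    c: np.ndarray               # contemporary-group effects (0 if unrecorded)
    eps: np.ndarray             # animal-level residuals

    def frame(self) -> pd.DataFrame:
        out = self.meta[["animal_id", "line", "litter", "cg"]].copy()
        for j, t in enumerate(self.traits):
            out[f"u_{t}"] = self.u[:, j]
            out[f"l_{t}"] = self.l[:, j]
            out[f"c_{t}"] = self.c[:, j]
            out[f"eps_{t}"] = self.eps[:, j]
        return out


def _sqrt_psd(M: np.ndarray) -> np.ndarray:
    """Symmetric PSD square root (works for singular covariance matrices)."""
    w, V = np.linalg.eigh(np.asarray(M, dtype=float))
    return V @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ V.T


def simulate_effects(simped: SimPedigree, cfg: SimConfig) -> TrueEffects:
    """Draw u, l, c and animal residuals with the configured covariances.

    Breeding values follow u_i = 0.5 (u_s + u_d) + m_i with
    Var(m_i) = d_i * G and d_i = 1 - 0.25 * sum_p (1 + F_p) over known
    parents (so Var(u) = A ⊗ G in expectation); litter effects are shared
    by litter mates, contemporary-group effects by off-test batch.
    """
    ped = simped.pedigree
    meta = assign_groups(simped.meta, cfg)
    rng = _rng(cfg, "effects")
    k = len(cfg.traits)
    n = ped.n
    Gs = _sqrt_psd(cfg.G_true)
    F = inbreeding(ped)

    u = np.zeros((n, k))
    z = rng.standard_normal((n, k))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        dd = 1.0
        mean = np.zeros(k)
        for p in (s, d):
            if p >= 0:
                dd -= 0.25 * (1.0 + F[p])
                mean += 0.5 * u[p]
        u[i] = mean + np.sqrt(dd) * (Gs @ z[i])

    # meta rows are in pedigree storage order by construction
    pos = ped.index_of(meta["animal_id"].to_numpy())
    u = u[pos]

    def per_level(codes: np.ndarray, cov: np.ndarray) -> np.ndarray:
        out = np.zeros((len(codes), k))
        levels = np.unique(codes[codes >= 0])
        if len(levels):
            draws = rng.standard_normal((len(levels), k)) @ _sqrt_psd(cov).T
            lut = {lev: j for j, lev in enumerate(levels)}
            mask = codes >= 0
            out[mask] = draws[[lut[c] for c in codes[mask]]]
        return out

    litter = meta["litter"].to_numpy()
    cg = meta["cg"].to_numpy()
    l = per_level(litter, cfg.L_true)
    c = per_level(cg, cfg.C_true)
    eps = rng.standard_normal((len(meta), k)) @ _sqrt_psd(cfg.R_true).T
    return TrueEffects(meta=meta, traits=list(cfg.traits), u=u, l=l, c=c, eps=eps)


def simulate_animal_phenotypes(eff: TrueEffects, cfg: SimConfig) -> pd.DataFrame:
    """One model-scale phenotype per recorded animal per trait (no flooring)."""
    rec = eff.meta["recorded"].to_numpy()
    meta = eff.meta.loc[rec, ["animal_id", "line", "litter", "cg"]].reset_index(drop=True)
    total = eff.u[rec] + eff.l[rec] + eff.c[rec] + eff.eps[rec]
    mu = cfg.line_means[eff.meta.loc[rec, "line"].to_numpy()]
    out = meta.copy()
    for j, t in enumerate(eff.traits):
        out[t] = mu[:, j] + total[:, j]
    return out


@dataclass
class SimData:
    """Everything one simulation run produces, including ground truth."""

    config: SimConfig
    pedigree: Pedigree
    meta: pd.DataFrame
    effects: TrueEffects
    records: pd.DataFrame | None        # day-wise table (day_level mode)
    phenotypes: pd.DataFrame | None     # animal-level table (animal_level mode)
    covariates: pd.DataFrame | None     # line/litter/off-test/production traits
    defects: pd.DataFrame | None        # per-record defect flags (sidecar)
    learning_period_end: object = None  # date; first day after learning groups
    learning_group_ids: tuple = ()
    flooring_rate: float = 0.0


def _ar1_noise(rng, shape, rho: float) -> np.ndarray:
    """Stationary AR(1) noise with unit marginal variance, shape (..., n_days)."""
    z = rng.standard_normal(shape)
    if rho == 0.0:
        return z
    x = np.empty_like(z)
    x[..., 0] = z[..., 0]
    a = np.sqrt(1.0 - rho**2)
    for d in range(1, shape[-1]):
        x[..., d] = rho * x[..., d - 1] + a * z[..., d]
    return x


def simulate_day_records(eff: TrueEffects, cfg: SimConfig):
    """Day-wise behavior records with injected defects.

    Returns ``(records, defects)``: the record table in the fixed CSV
    column order and a per-record sidecar of defect flags.  Per animal-day
    values are line mean + age trend + u + l + c + eps + AR(1) day noise,
    floored at 0; the four posture times are rescaled to close exactly on
    the recording time.
    """
    if cfg.mode != "day_level":
        raise ConfigError("simulate_day_records requires mode='day_level'")
    missing = set(eff.meta["animal_id"]) - set(np.asarray(eff.meta["animal_id"]))
    if missing:  # pragma: no cover - defensive
        raise ConfigError(f"effects contain unknown animals: {missing}")
    rng = _rng(cfg, "days")
    traits = [t for t in eff.traits if t in BEHAVIOR_TRAITS]
    tj = [eff.traits.index(t) for t in traits]
    rec_mask = eff.meta["recorded"].to_numpy()
    meta = eff.meta.loc[rec_mask].reset_index(drop=True)
    n, k, nd = len(meta), len(traits), cfg.n_test_days
    full_min = cfg.daily_hours * 60.0

    days = np.arange(1, nd + 1, dtype=float)
    dc = days - (nd + 1) / 2.0  # centred day on test
    trend = np.zeros((k, nd))
    for j, t in enumerate(traits):
        lin, quad = cfg.trend.get(t, (0.0, 0.0))
        trend[j] = lin * dc + quad * (dc**2 - np.mean(dc**2))

    base = eff.u[rec_mask][:, tj] + eff.l[rec_mask][:, tj] \
        + eff.c[rec_mask][:, tj] + eff.eps[rec_mask][:, tj]
    mu = cfg.line_means[meta["line"].to_numpy()][:, tj]
    sd = cfg.day_noise_sd[tj]

    vals = np.empty((n, nd, k))
    noise = _ar1_noise(rng, (n, k, nd), cfg.day_noise_ar1)
    for j in range(k):
        vals[:, :, j] = (mu[:, j] + base[:, j])[:, None] + trend[j][None, :] \
            + sd[j] * noise[:, j, :]
    floored = vals < 0
    flooring_rate = float(floored.mean())
    vals = np.maximum(vals, 0.0)

    # posture-sum closure: the four postures partition the recording day
    pj = [traits.index(t) for t in POSTURE_TRAITS if t in traits]
    if len(pj) == len(POSTURE_TRAITS):
        psum = vals[:, :, pj].sum(axis=2)
        bad = psum <= 0
        if bad.any():
            for j in pj:
                vals[:, :, j][bad] = full_min / len(pj)
            psum = vals[:, :, pj].sum(axis=2)
        scale = full_min / psum
        for j in pj:
            vals[:, :, j] *= scale

    minutes = np.full((n, nd), full_min)
    short = rng.random((n, nd)) < cfg.p_short_day
    lo, hi = cfg.short_day_hours_range
    minutes[short] = rng.uniform(lo * 60.0, hi * 60.0, size=int(short.sum()))
    vals *= (minutes / full_min)[:, :, None]  # shorter window, less of everything

    # genuine movement cannot exceed the physical distance-per-standing-time
    # bound; the sitting-rotation artifact then inflates distance beyond it
    dist_j = traits.index("distance") if "distance" in traits else None
    stand_j = traits.index("standing") if "standing" in traits else None
    artifact = np.zeros((n, nd), dtype=bool)
    if dist_j is not None and stand_j is not None:
        vals[:, :, dist_j] = np.minimum(
            vals[:, :, dist_j], cfg.max_distance_rate * vals[:, :, stand_j])
        if cfg.p_distance_artifact > 0:
            artifact = rng.random((n, nd)) < cfg.p_distance_artifact
            excess = rng.uniform(5.0, 600.0, size=int(artifact.sum()))
            vals[:, :, dist_j][artifact] = (
                cfg.max_distance_rate * vals[:, :, stand_j][artifact] + excess)

    culled = rng.random(n) < cfg.p_cull
    cull_day = np.where(culled, rng.integers(2, nd, size=n), nd + 1)

    groups = meta["recording_group"].to_numpy()
    n_groups = int(groups.max()) + 1
    k_learn = min(cfg.learning_groups, n_groups)
    starts = {}
    cutoff = cfg.start_date + timedelta(days=7 * max(k_learn - 1, 0) + nd)
    for g in range(n_groups):
        if g < k_learn:
            starts[g] = cfg.start_date + timedelta(days=7 * g)
        else:
            starts[g] = cutoff + timedelta(days=7 * (g - k_learn))
    learning_ids = tuple(f"G{g:03d}" for g in range(k_learn))

    keep = days[None, :] <= cull_day[:, None]
    ai, di = np.nonzero(keep)
    day_idx = (di + 1).astype(int)
    rec = pd.DataFrame({
        "animal_id": meta["animal_id"].to_numpy()[ai],
        "group_id": [f"G{g:03d}" for g in groups[ai]],
        "date": [starts[g] + timedelta(days=int(d) - 1)
                 for g, d in zip(groups[ai], day_idx)],
        "day_index": day_idx,
        "recording_minutes": minutes[ai, di],
    })
    for j, t in enumerate(traits):
        rec[RECORD_COLUMNS[t]] = vals[ai, di, j]
    rec["culled_today"] = day_idx == cull_day[ai]
    for col in DAY_RECORD_HEADER:
        if col not in rec.columns:
            rec[col] = 0.0
    rec = rec[DAY_RECORD_HEADER]

    defects = pd.DataFrame({
        "animal_id": rec["animal_id"],
        "group_id": rec["group_id"],
        "day_index": rec["day_index"],
        "learning": np.isin(rec["group_id"], learning_ids),
        "short_day": short[ai, di],
        "recording_minutes": minutes[ai, di],
        "cull_day": rec["culled_today"].to_numpy(),
        "boundary": (day_idx == 1) | (day_idx == nd),
        "distance_artifact": artifact[ai, di],
    })
    rec.attrs["learning_period_end"] = cutoff
    rec.attrs["flooring_rate"] = flooring_rate
    return rec, defects


def simulate_production(eff: TrueEffects, cfg: SimConfig,
                        starts: dict | None = None) -> pd.DataFrame:
    """Per-animal covariate table: line, litter, off-test date, production traits."""
    rec = eff.meta["recorded"].to_numpy()
    meta = eff.meta.loc[rec].reset_index(drop=True)
    out = meta[["animal_id", "line", "litter", "cg", "recording_group"]].copy()
    if starts:
        out["off_test_date"] = [starts[g] + timedelta(days=cfg.n_test_days)
                                for g in meta["recording_group"]]
    prod = [t for t in eff.traits if t in cfg.production_traits]
    mu = cfg.line_means[meta["line"].to_numpy()]
    for t in prod:
        j = eff.traits.index(t)
        out[t] = (mu[:, j] + eff.u[rec][:, j] + eff.l[rec][:, j]
                  + eff.c[rec][:, j] + eff.eps[rec][:, j])
    return out


def simulate_dataset(cfg: SimConfig) -> SimData:
    """Run the full generator for the configured mode."""
    simped = simulate_pedigree(cfg)
    eff = simulate_effects(simped, cfg)
    records = phenos = defects = None
    learning_end = None
    learning_ids = ()
    floor_rate = 0.0
    if cfg.mode == "day_level":
        records, defects = simulate_day_records(eff, cfg)
        learning_end = records.attrs["learning_period_end"]
        floor_rate = records.attrs["flooring_rate"]
        learning_ids = tuple(sorted(defects.loc[defects["learning"], "group_id"]
                                    .unique()))
    else:
        phenos = simulate_animal_phenotypes(eff, cfg)
    covars = simulate_production(eff, cfg)
    return SimData(config=cfg, pedigree=simped.pedigree, meta=eff.meta,
                   effects=eff, records=records, phenotypes=phenos,
                   covariates=covars, defects=defects,
                   learning_period_end=learning_end,
                   learning_group_ids=learning_ids,
                   flooring_rate=floor_rate)


def write_records(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False, columns=DAY_RECORD_HEADER)


def write_truth(eff: TrueEffects, path) -> None:
    eff.frame().to_csv(path, index=False)
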