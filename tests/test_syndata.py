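"""Synthetic-data generator: structure, determinism, variance calibration."""

import numpy as np
import pandas as pd
import pytest

from penphen.config import POSTURE_TRAITS, RECORD_COLUMNS, ConfigError, SimConfig
from penphen.pedigree import build_A
from penphen.syndata import (SimPedigree, assign_groups, simulate_dataset,
                             simulate_day_records, simulate_effects,
                             simulate_pedigree)


def day_cfg(**kw):
    base = dict(n_founders=40, n_generations=2, n_litters_per_gen=12,
                litter_size_mean=6, n_test_days=30, group_size=10,
                n_contemp_groups=5, mode="day_level", seed=3)
    base.update(kw)
    return SimConfig(**base)


class TestPedigreeSim:
    def test_zero_generations_all_founders(self):
        cfg = SimConfig(n_founders=10, n_generations=0, seed=1)
        sp = simulate_pedigree(cfg)
        assert sp.pedigree.n == 10
        assert np.all(sp.pedigree.sire == -1) and np.all(sp.pedigree.dam == -1)

    def test_seeded_determinism_byte_identical(self):
        cfg = SimConfig(n_founders=10, n_generations=2, n_litters_per_gen=4, seed=1)
        a = simulate_pedigree(cfg).pedigree.to_frame()
        b = simulate_pedigree(cfg).pedigree.to_frame()
        pd.testing.assert_frame_equal(a, b)

    def test_topological_order_by_dfs_oracle(self):
        cfg = SimConfig(n_founders=30, n_generations=3, n_litters_per_gen=8, seed=9)
        ped = simulate_pedigree(cfg).pedigree
        # independent check: walk ancestors depth-first, no animal may
        # reach itself and every parent index must precede the child
        for i in range(ped.n):
            stack, seen = [i], set()
            while stack:
                j = stack.pop()
                for p in (ped.sire[j], ped.dam[j]):
                    if p >= 0:
                        assert p < j or j != i or p not in seen
                        assert p != i, "animal is its own ancestor"
                        if p not in seen:
                            seen.add(p)
                            stack.append(p)
        assert ped.is_sorted()

    def test_litter_mates_share_parents(self):
        cfg = SimConfig(n_founders=20, n_generations=1, n_litters_per_gen=6, seed=2)
        sp = simulate_pedigree(cfg)
        df = sp.pedigree.to_frame().merge(sp.meta, left_on="animal", right_on="animal_id")
        kids = df[df["litter"] >= 0]
        per_litter = kids.groupby("litter")[["sire", "dam"]].nunique()
        assert (per_litter == 1).all().all()

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(n_founders=1)
        with pytest.raises(ConfigError):
            SimConfig(n_test_days=2)


class TestEffects:
    def test_zero_G_gives_zero_breeding_values(self):
        cfg = SimConfig(traits=["eating"], G_true=np.zeros((1, 1)),
                        n_founders=20, n_generations=1, n_litters_per_gen=5,
                        seed=4)
        eff = simulate_effects(simulate_pedigree(cfg), cfg)
        assert np.all(eff.u == 0.0)

    def test_founder_breeding_value_variance(self):
        # chi-square bound on the sample variance at n = 5000, alpha ~ 0.01
        cfg = SimConfig(traits=["x"], G_true=np.eye(1), L_true=np.zeros((1, 1)),
                        C_true=np.zeros((1, 1)), R_true=np.zeros((1, 1)),
                        line_means=np.zeros((2, 1)),
                        n_founders=5000, n_generations=0, seed=5)
        eff = simulate_effects(simulate_pedigree(cfg), cfg)
        assert 0.92 <= eff.u.var(ddof=1) <= 1.08

    def test_full_sib_covariance_half_G(self):
        # 4000 independent founder pairs, two offspring each: the sample
        # covariance between sibs estimates 0.5 * G
        n_pairs = 4000
        triples, meta_rows = [], []
        aid = 1
        for k in range(n_pairs):
            s, d = aid, aid + 1
            triples += [(s, 0, 0), (d, 0, 0), (aid + 2, s, d), (aid + 3, s, d)]
            for a, g, lit in ((s, 0, -1), (d, 0, -1), (aid + 2, 1, k),
                              (aid + 3, 1, k)):
                meta_rows.append((a, 0, g, lit, "F"))
            aid += 4
        from penphen.pedigree import Pedigree
        ped = Pedigree.from_triples(triples)
        meta = pd.DataFrame(meta_rows, columns=["animal_id", "line",
                                                "generation", "litter", "sex"])
        cfg = SimConfig(traits=["x"], G_true=np.eye(1), L_true=np.zeros((1, 1)),
                        C_true=np.zeros((1, 1)), R_true=np.zeros((1, 1)),
                        line_means=np.zeros((2, 1)), n_founders=4,
                        n_generations=0, seed=6)
        eff = simulate_effects(SimPedigree(ped, meta), cfg)
        sib1 = eff.u[2::4, 0]
        sib2 = eff.u[3::4, 0]
        cov = np.cov(sib1, sib2)[0, 1]
        assert cov == pytest.approx(0.5, abs=3.0 / np.sqrt(n_pairs))

    def test_litter_and_group_effects_shared(self):
        cfg = day_cfg()
        eff = simulate_effects(simulate_pedigree(cfg), cfg)
        df = eff.meta.assign(l0=eff.l[:, 0], c0=eff.c[:, 0])
        lit = df[df["litter"] >= 0].groupby("litter")["l0"].nunique()
        assert (lit == 1).all()
        cgs = df[df["cg"] >= 0].groupby("cg")["c0"].nunique()
        assert (cgs == 1).all()

    def test_non_psd_matrix_rejected(self):
        with pytest.raises(ConfigError, match="positive semi-definite"):
            SimConfig(traits=["a", "b"],
                      G_true=np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestDayRecords:
    def test_defect_free_records_full_minutes(self):
        cfg = day_cfg(p_short_day=0, p_cull=0, p_distance_artifact=0)
        sim = simulate_dataset(cfg)
        rec = sim.records
        assert (rec["recording_minutes"] == 840.0).all()
        assert not rec["culled_today"].any()
        ratio_ok = rec["distance_m"] <= 15.0 * rec["standing_min"] + 1e-9
        assert ratio_ok.all()

    def test_posture_sum_closure(self):
        cfg = day_cfg(p_short_day=0.2, p_cull=0.1, p_distance_artifact=0.05)
        rec, _ = simulate_day_records(
            simulate_effects(simulate_pedigree(cfg), cfg), cfg)
        psum = sum(rec[RECORD_COLUMNS[t]] for t in POSTURE_TRAITS)
        assert np.abs(psum - rec["recording_minutes"]).max() < 1e-6

    def test_seeded_reproducibility(self):
        cfg = day_cfg(p_short_day=0.1, p_cull=0.1, p_distance_artifact=0.02)
        a = simulate_dataset(cfg).records
        b = simulate_dataset(cfg).records
        pd.testing.assert_frame_equal(a, b)

    def test_culled_animals_stop_and_are_flagged(self):
        cfg = day_cfg(p_cull=0.5)
        sim = simulate_dataset(cfg)
        rec = sim.records
        last = rec.groupby("animal_id").agg(last_day=("day_index", "max"),
                                            n_cull=("culled_today", "sum"))
        culled = last[last["last_day"] < cfg.n_test_days]
        assert (culled["n_cull"] == 1).all()
        assert len(culled) > 0

    def test_artifact_rate_converges(self):
        cfg = day_cfg(n_founders=60, n_litters_per_gen=20, p_distance_artifact=0.03)
        sim = simulate_dataset(cfg)
        viol = (sim.records["distance_m"]
                > 15.0 * sim.records["standing_min"] + 1e-9)
        rate = viol.mean()
        n = len(sim.records)
        assert abs(rate - 0.03) < 4 * np.sqrt(0.03 * 0.97 / n)

    def test_grand_mean_eating_near_calibration(self):
        # default calibration: mean daily eating time 56.41 min; the grand
        # mean over a defect-free run stays within 3 SEs of that value
        cfg = SimConfig(n_founders=200, n_generations=2, n_litters_per_gen=50,
                        mode="day_level", seed=11)
        sim = simulate_dataset(cfg)
        per_animal = sim.records.groupby("animal_id")["eating_min"].mean()
        sem = 19.55 / np.sqrt(len(per_animal))
        assert abs(per_animal.mean() - 56.41) < 3 * sem
        # zero-flooring emulates the pile-up at 0 of short-duration traits
        # (sitting, drinking); it stays a small fraction of all values
        assert sim.flooring_rate < 0.05

    def test_learning_groups_tagged_and_dated(self):
        cfg = day_cfg(learning_groups=2)
        sim = simulate_dataset(cfg)
        assert len(sim.learning_group_ids) == 2
        dates = pd.to_datetime(sim.records["date"]).dt.date
        learn = sim.records["group_id"].isin(sim.learning_group_ids)
        assert dates[learn].max() < sim.learning_period_end
        assert dates[~learn].min() >= sim.learning_period_end


class TestAnimalLevel:
    def test_component_variances_match_truth(self):
        cfg = SimConfig(traits=["x"], G_true=np.eye(1) * 0.4,
                        L_true=np.eye(1) * 0.1, C_true=np.eye(1) * 0.05,
                        R_true=np.eye(1) * 0.45, line_means=np.zeros((2, 1)),
                        n_founders=400, n_generations=2, n_litters_per_gen=150,
                        litter_size_mean=8, seed=12)
        sim = simulate_dataset(cfg)
        eff = sim.effects
        rec = eff.meta["recorded"].to_numpy()
        # residuals and litter draws are i.i.d. with the configured variances
        assert eff.eps[rec].var(ddof=1) == pytest.approx(0.45, rel=0.15)
        lit_vals = (pd.DataFrame({"lit": eff.meta["litter"], "l": eff.l[:, 0]})
                    .query("lit >= 0").groupby("lit")["l"].first())
        assert lit_vals.var(ddof=1) == pytest.approx(0.1, rel=0.25)
        # phenotypic variance assembles all four components
        assert sim.phenotypes["x"].var(ddof=1) == pytest.approx(1.0, rel=0.15)

    def test_breeding_value_variance_tracks_A(self):
        cfg = SimConfig(traits=["x"], G_true=np.eye(1), L_true=np.zeros((1, 1)),
                        C_true=np.zeros((1, 1)), R_true=np.zeros((1, 1)),
                        line_means=np.zeros((2, 1)), n_founders=30,
                        n_generations=2, n_litters_per_gen=10, seed=13)
        sp = simulate_pedigree(cfg)
        reps = [simulate_effects(sp, SimConfig(**{**cfg.__dict__, "seed": s}))
                .u[:, 0] for s in range(150)]
        U = np.stack(reps)  # (reps, animals)
        emp = (U * U).mean(axis=0)          # E[u_i^2] = A_ii * G
        diag = np.diag(build_A(sp.pedigree).A)
        # expected mean absolute MC deviation ~ 0.8 * A_ii * sqrt(2/150)
        assert np.abs(emp - diag).mean() < 0.2
        assert abs((emp - diag).mean()) < 0.05
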