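"""REML engine: closed-form oracles, invariances, sampling behavior."""

import numpy as np
import pandas as pd
import pytest

from penphen.pedigree import Pedigree, build_A_inverse
from penphen.pipeline import recovery_config
from penphen.syndata import simulate_dataset
from penphen.varcomp import (CovarianceComponents, DesignError,
                             VarianceComponents, build_design, correlations,
                             heritability, raw_phenotypic_correlation,
                             reml_fit_single, reml_fit_two_trait)


def founder_pedigree(n):
    return Pedigree.from_triples([(i, 0, 0) for i in range(1, n + 1)])


def two_gen_dataset(trait_cfg, seed=0, n_founders=80, n_litters=20,
                    litter_size=6.0):
    """Small animal-level simulation; returns (phenotypes, pedigree, A_inv)."""
    cfg = recovery_config(**trait_cfg, seed=seed, n_founders=n_founders,
                          n_generations=2, n_litters_per_gen=n_litters,
                          litter_size_mean=litter_size, n_contemp_groups=6)
    sim = simulate_dataset(cfg)
    return sim.phenotypes, sim.pedigree, build_A_inverse(sim.pedigree)


class TestBuildDesign:
    PHENO = pd.DataFrame({
        "animal_id": [1, 2, 3, 4, 5, 6], "line": [0, 0, 0, 1, 1, 1],
        "litter": [0, 0, 1, 1, 2, 2], "cg": [0, 0, 0, 1, 1, 1],
        "y": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]})

    def test_level_counts(self):
        d = build_design(self.PHENO, ["y"], pedigree=founder_pedigree(6))
        assert d.X[0].shape == (6, 2)       # intercept + 1 line contrast
        assert d.n_litters == 3 and d.n_cg == 2

    def test_single_cg_still_estimable(self):
        df = self.PHENO.assign(cg=0)
        d = build_design(df, ["y"], pedigree=founder_pedigree(6))
        assert d.n_cg == 1

    def test_confounded_litter_cg_rejected(self):
        df = self.PHENO.assign(cg=self.PHENO["litter"])
        with pytest.raises(DesignError, match="identical partition"):
            build_design(df, ["y"], pedigree=founder_pedigree(6))


class TestClosedForms:
    def test_fixed_effects_only_residual_is_ols_variance(self):
        rng = np.random.default_rng(5)
        n = 60
        line = np.repeat([0, 1], n // 2)
        y = 2.0 + 1.5 * line + rng.normal(0, 0.8, n)
        pheno = pd.DataFrame({"animal_id": np.arange(1, n + 1), "line": line,
                              "litter": 0, "cg": 0, "y": y})
        d = build_design(pheno, ["y"], pedigree=founder_pedigree(n),
                         random_terms=())
        vc = reml_fit_single(None, d, tol=1e-12, max_iter=100)
        X = np.column_stack([np.ones(n), line])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(((y - X @ beta) ** 2).sum())
        expected = rss / (n - 2)
        assert vc["residual"] == pytest.approx(expected, rel=1e-8)

    def test_balanced_sire_model_equals_anova(self):
        # s unrelated sires with n offspring each: REML = ANOVA estimators
        # sigma2_sire = (MSB - MSW) / n, sigma2_e = MSW
        rng = np.random.default_rng(11)
        s, n = 8, 20
        sire_eff = rng.normal(0, 0.7, s)
        y = (sire_eff[:, None] + rng.normal(0, 1.0, (s, n))).ravel()
        sire_id = np.repeat(np.arange(1, s + 1), n)
        pheno = pd.DataFrame({"animal_id": sire_id, "line": 0, "litter": 0,
                              "cg": 0, "y": y})
        ped = founder_pedigree(s)
        d = build_design(pheno, ["y"], pedigree=ped,
                         random_terms=("additive",))
        vc = reml_fit_single(None, d, A_inv=build_A_inverse(ped),
                             tol=1e-12, max_iter=200)
        means = y.reshape(s, n).mean(axis=1)
        msb = n * means.var(ddof=1)
        msw = (y.reshape(s, n) - means[:, None]).var(ddof=0) * n * s / (s * (n - 1))
        assert vc["residual"] == pytest.approx(msw, rel=1e-6)
        assert vc["additive"] == pytest.approx((msb - msw) / n, rel=1e-6)


class TestBoundary:
    def test_zero_additive_variance_estimates_near_boundary(self):
        # truth sigma2_u = 0 on a two-generation family design: estimates
        # sit at or near the zero boundary (< 10% of phenotypic variance)
        # in >= 90% of 50 replicates
        at_boundary = 0
        for rep in range(50):
            pheno, ped, A_inv = two_gen_dataset(
                dict(traits=["y"], h2=[0.0]), seed=500 + rep,
                n_founders=120, n_litters=30, litter_size=7.0)
            d = build_design(pheno, ["y"], pedigree=ped)
            vc = reml_fit_single(None, d, A_inv=A_inv, tol=1e-6)
            at_boundary += vc["additive"] < 0.1
        assert at_boundary >= 45


class TestTwoTrait:
    def test_independent_traits_mean_rg_near_zero(self):
        rgs = []
        for rep in range(20):
            pheno, ped, A_inv = two_gen_dataset(
                dict(traits=["a", "b"], h2=[0.4, 0.4], r_g=0.0),
                seed=100 + rep)
            d = build_design(pheno, ["a", "b"], pedigree=ped)
            cc = reml_fit_two_trait(None, None, d, A_inv=A_inv, tol=1e-6)
            rgs.append(correlations(cc)["r_g"])
        rgs = np.asarray(rgs)
        assert abs(rgs.mean()) < 3 * rgs.std(ddof=1) / np.sqrt(len(rgs))

    def test_constrained_cross_matches_single_fits(self):
        pheno, ped, A_inv = two_gen_dataset(
            dict(traits=["a", "b"], h2=[0.45, 0.3], r_g=0.5), seed=7)
        d2 = build_design(pheno, ["a", "b"], pedigree=ped)
        cc = reml_fit_two_trait(None, None, d2, A_inv=A_inv, tol=1e-10,
                                fix_cross=("additive", "litter", "cg",
                                           "residual"))
        for j, t in enumerate(["a", "b"]):
            d1 = build_design(pheno, [t], pedigree=ped)
            vc = reml_fit_single(None, d1, A_inv=A_inv, tol=1e-10)
            for term in ("additive", "litter", "cg", "residual"):
                # abs floor covers components at the zero boundary, where
                # a relative tolerance is meaningless
                assert cc.matrices[term][j, j] == pytest.approx(
                    vc[term], rel=1e-4, abs=1e-6)

    def test_duplicate_trait_genetic_correlation_near_one(self):
        pheno, ped, A_inv = two_gen_dataset(
            dict(traits=["a"], h2=[0.5]), seed=9)
        rng = np.random.default_rng(1)
        pheno = pheno.assign(b=pheno["a"] + rng.normal(0, 0.05, len(pheno)))
        d = build_design(pheno, ["a", "b"], pedigree=ped)
        cc = reml_fit_two_trait(None, None, d, A_inv=A_inv, tol=1e-8)
        assert correlations(cc)["r_g"] > 0.99

    def test_missing_records_for_one_trait_handled(self):
        pheno, ped, A_inv = two_gen_dataset(
            dict(traits=["a", "b"], h2=[0.4, 0.4], r_g=0.6), seed=13)
        pheno = pheno.copy()
        pheno.loc[pheno.index[::4], "b"] = np.nan   # 25% missing at random
        d = build_design(pheno, ["a", "b"], pedigree=ped)
        assert len(d.y[1]) < len(d.y[0])
        cc = reml_fit_two_trait(None, None, d, A_inv=A_inv, tol=1e-6)
        assert cc.convergence.converged
        assert -1.0 <= correlations(cc)["r_g"] <= 1.0


class TestInvariances:
    def test_scale_equivariance(self):
        pheno, ped, A_inv = two_gen_dataset(
            dict(traits=["a"], h2=[0.4]), seed=21)
        k = 3.7
        d1 = build_design(pheno, ["a"], pedigree=ped)
        d2 = build_design(pheno.assign(a=pheno["a"] * k), ["a"], pedigree=ped)
        v1 = reml_fit_single(None, d1, A_inv=A_inv, tol=1e-10)
        v2 = reml_fit_single(None, d2, A_inv=A_inv, tol=1e-10)
        for term in v1.components:
            assert v2[term] == pytest.approx(k**2 * v1[term], rel=1e-6)
        h1, _ = heritability(v1)
        h2_, _ = heritability(v2)
        assert h2_ == pytest.approx(h1, abs=1e-6)

    def test_likelihood_ascent(self):
        pheno, ped, A_inv = two_gen_dataset(
            dict(traits=["a", "b"], h2=[0.43, 0.38], r_g=0.93), seed=23)
        d = build_design(pheno, ["a", "b"], pedigree=ped)
        cc = reml_fit_two_trait(None, None, d, A_inv=A_inv, tol=1e-8)
        path = np.asarray(cc.convergence.loglik_path)
        assert np.all(np.diff(path) >= -1e-9 * np.abs(path[:-1]))

    def test_permutation_invariance(self):
        pheno, ped, A_inv = two_gen_dataset(
            dict(traits=["a"], h2=[0.4]), seed=25)
        shuffled = pheno.sample(frac=1.0, random_state=4).reset_index(drop=True)
        v1 = reml_fit_single(None, build_design(pheno, ["a"], pedigree=ped),
                             A_inv=A_inv, tol=1e-10)
        v2 = reml_fit_single(None, build_design(shuffled, ["a"], pedigree=ped),
                             A_inv=A_inv, tol=1e-10)
        for term in v1.components:
            assert v2[term] == pytest.approx(v1[term], abs=1e-8)


class TestDerived:
    def make_vc(self, u, l, c, e):
        comps = {"additive": u, "litter": l, "cg": c, "residual": e}
        idx = {n: i for i, n in enumerate(comps)}
        return VarianceComponents(components=comps, se={n: 0.0 for n in comps},
                                  cov=np.zeros((4, 4)), param_index=idx,
                                  convergence=None)

    def test_heritability_arithmetic(self):
        h2, _ = heritability(self.make_vc(0.57, 0.05, 0.05, 0.33))
        assert h2 == pytest.approx(0.57)
        h2, _ = heritability(self.make_vc(0.0, 0.2, 0.3, 0.5))
        assert h2 == 0.0
        h2, _ = heritability(self.make_vc(0.57, 0.05, 0.05, 0.33),
                             denominator_mode="no_cg")
        assert h2 == pytest.approx(0.57 / 0.95)
        with pytest.raises(ZeroDivisionError):
            heritability(self.make_vc(0.0, 0.0, 0.0, 0.0))

    def make_cc(self, G, L, C, R):
        mats = {"additive": np.asarray(G, float), "litter": np.asarray(L, float),
                "cg": np.asarray(C, float), "residual": np.asarray(R, float)}
        idx = {}
        k = 0
        for name in mats:
            for a, b in ((0, 0), (0, 1), (1, 1)):
                idx[(name, a, b)] = k
                k += 1
        return CovarianceComponents(traits=["a", "b"], matrices=mats,
                                    cov=np.zeros((k, k)), param_index=idx,
                                    convergence=None)

    def test_correlation_arithmetic(self):
        eye2 = np.eye(2) * 0.1
        cc = self.make_cc([[1, 0.93], [0.93, 1]], eye2, eye2, np.eye(2))
        out = correlations(cc)
        assert out["r_g"] == pytest.approx(0.93)
        assert out["r_p"] == pytest.approx(0.93 / 2.2)
        cc0 = self.make_cc(np.eye(2), eye2, eye2, np.eye(2))
        assert correlations(cc0)["r_p"] == 0.0

    def test_component_sum_rp_matches_pearson_at_large_n(self):
        cfg = recovery_config(["a", "b"], [0.4, 0.4], r_g=0.5, r_p=0.4,
                              seed=29, n_founders=600, n_generations=2,
                              n_litters_per_gen=280, litter_size_mean=8,
                              n_contemp_groups=20)
        sim = simulate_dataset(cfg)
        assert len(sim.phenotypes) >= 4000
        r_raw = raw_phenotypic_correlation(sim.phenotypes, "a", "b")
        assert r_raw == pytest.approx(0.4, abs=3.0 / np.sqrt(4000))

    def test_delta_se_matches_parametric_bootstrap(self):
        # 150-replicate parametric bootstrap of h2 on a fixed two-generation
        # design vs the average delta-method SE
        ses, ests = [], []
        for rep in range(150):
            pheno, ped, A_inv = two_gen_dataset(
                dict(traits=["a"], h2=[0.4], litter_frac=0.1, cg_frac=0.0),
                seed=3000 + rep, n_founders=60, n_litters=20, litter_size=6.0)
            d = build_design(pheno, ["a"], pedigree=ped,
                             random_terms=("additive", "litter"))
            vc = reml_fit_single(None, d, A_inv=A_inv, tol=1e-6)
            h2, se = heritability(vc)
            ests.append(h2)
            ses.append(se)
        emp_sd = np.std(ests, ddof=1)
        assert np.mean(ses) == pytest.approx(emp_sd, rel=0.25)
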