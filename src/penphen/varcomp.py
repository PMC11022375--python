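"""REML variance components for single- and two-trait animal models.

The model is ``y = X b + Z u + W1 l + W2 c + e`` with fixed line effects
and random additive-genetic (covariance ``A sigma2_u``, or ``A ⊗ G`` for
two traits), common-litter, contemporary-group and residual effects.

Estimation is average-information (AI) REML on the marginal covariance
``V = sum_s M_s ∘ K_s`` (trait-covariance matrices M against fixed
observation-level kernels K).  AI (Newton) steps are taken on a
log-Cholesky parameterization so every proposal maps back inside the
positive-semi-definite cone; a likelihood-ascent backtracking guard
shortens any step that would decrease the restricted likelihood and
falls back to an EM-REML step when the AI direction fails outright.
Eigenvalue bending keeps near-singular trait-covariance matrices
numerically safe.  Standard errors come from the inverse AI matrix at
convergence; heritabilities and genetic correlations carry delta-method
standard errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp

from .pedigree import relationship_submatrix

log = logging.getLogger(__name__)

RANDOM_TERMS = ("additive", "litter", "cg")


class DesignError(ValueError):
    """Unusable model design (rank deficiency, confounded factors)."""


# --------------------------------------------------------------- design

@dataclass
class ModelDesign:
    """Observation-level design for 1 or 2 traits.

    Per trait: response vector, fixed-effect matrix (intercept + line
    corner-point coding), and integer codes mapping observations to
    pedigree position, litter level and contemporary-group level.
    """

    traits: list
    y: list                      # per-trait response arrays
    X: list                      # per-trait fixed-design arrays
    animal: list                 # per-trait obs -> pedigree position
    litter: list | None
    cg: list | None
    include: tuple               # random terms in the model
    n_litters: int = 0
    n_cg: int = 0

    @property
    def n_traits(self) -> int:
        return len(self.traits)


def build_design(phenotypes: pd.DataFrame, traits, pedigree=None,
                 random_terms: tuple = RANDOM_TERMS) -> ModelDesign:
    """Assemble a ModelDesign from a phenotype table.

    `phenotypes` needs columns animal_id, line, litter, cg plus one column
    per requested trait; rows missing a trait are dropped for that trait
    only (missing-at-random bivariate handling).  Raises DesignError when
    litter and contemporary group define the identical partition of the
    used observations.
    """
    traits = list(traits)
    if not 1 <= len(traits) <= 2:
        raise DesignError("build_design handles 1 or 2 traits")
    df = phenotypes.reset_index(drop=True)
    for col in ("animal_id", "line"):
        if col not in df.columns:
            raise DesignError(f"phenotypes lack required column {col!r}")

    line_levels = np.unique(df["line"].to_numpy())
    lit_levels = np.unique(df["litter"].to_numpy()) if "litter" in df else []
    cg_levels = np.unique(df["cg"].to_numpy()) if "cg" in df else []
    lit_code = {v: i for i, v in enumerate(lit_levels)}
    cg_code = {v: i for i, v in enumerate(cg_levels)}

    ys, Xs, animals, litters, cgs = [], [], [], [], []
    used_rows = set()
    for t in traits:
        if t not in df.columns:
            raise DesignError(f"trait {t!r} missing from phenotype table")
        keep = df[t].notna()
        for col in ("line", "litter", "cg"):
            if col in df.columns:
                keep &= df[col].notna()
        sub = df.loc[keep]
        used_rows |= set(sub.index)
        ys.append(sub[t].to_numpy(dtype=float))
        X = np.ones((len(sub), 1))
        for lev in line_levels[1:]:  # corner-point: first line in intercept
            X = np.hstack([X, (sub["line"].to_numpy() == lev)[:, None] * 1.0])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            X = X[:, :1]  # single line level present: intercept only
        Xs.append(X)
        if pedigree is not None:
            animals.append(pedigree.index_of(sub["animal_id"].to_numpy()))
        else:
            ids = {a: i for i, a in enumerate(np.unique(df["animal_id"]))}
            animals.append(np.array([ids[a] for a in sub["animal_id"]]))
        litters.append(np.array([lit_code[v] for v in sub["litter"]])
                       if "litter" in df else None)
        cgs.append(np.array([cg_code[v] for v in sub["cg"]])
                   if "cg" in df else None)

    include = tuple(t for t in random_terms if t in RANDOM_TERMS)
    if "litter" in include and litters[0] is None:
        raise DesignError("litter term requested but no litter column")
    if "cg" in include and cgs[0] is None:
        raise DesignError("cg term requested but no cg column")
    if "litter" in include and "cg" in include:
        sub = df.loc[sorted(used_rows)]
        pairs = sub[["litter", "cg"]].drop_duplicates()
        if (pairs["litter"].nunique() == len(pairs) ==
                pairs["cg"].nunique()):
            raise DesignError(
                "factors 'litter' and 'cg' define the identical partition "
                "of the observations; the model is not identifiable")
    return ModelDesign(traits=traits, y=ys, X=Xs, animal=animals,
                       litter=litters if litters[0] is not None else None,
                       cg=cgs if cgs[0] is not None else None,
                       include=include,
                       n_litters=len(lit_levels), n_cg=len(cg_levels))


# --------------------------------------------------------------- results

@dataclass
class ConvergenceRecord:
    converged: bool
    iterations: int
    loglik: float
    grad_norm: float
    step_norm: float
    loglik_path: list = field(default_factory=list)


@dataclass
class VarianceComponents:
    """Single-trait estimates sigma2 per term with AI-based SEs."""

    components: dict
    se: dict
    cov: np.ndarray
    param_index: dict            # term name -> position in cov
    convergence: ConvergenceRecord

    def __getitem__(self, term):
        return self.components[term]


@dataclass
class CovarianceComponents:
    """Two-trait 2x2 (co)variance matrices per term with sampling covariance."""

    traits: list
    matrices: dict               # term -> (2, 2) ndarray
    cov: np.ndarray              # sampling covariance of the free parameters
    param_index: dict            # (term, i, j) -> position in cov
    convergence: ConvergenceRecord


# ----------------------------------------------------------- REML engine

def _bend(M: np.ndarray, floor_scale: float, min_floor: float = 0.0) -> np.ndarray:
    """Project a symmetric matrix onto the PSD cone (eigenvalue flooring)."""
    M = 0.5 * (M + M.T)
    w, V = np.linalg.eigh(M)
    eps = max(1e-8 * max(np.trace(M), 0.0), min_floor) * floor_scale
    if w.min() >= eps:
        return M
    return V @ np.diag(np.maximum(w, eps)) @ V.T


class _REMLProblem:
    """Dense-V REML state shared by the single- and two-trait fits."""

    def __init__(self, design: ModelDesign, A_inv=None, fix_cross=()):
        nt = design.n_traits
        self.nt = nt
        self.design = design
        self.n_t = [len(y) for y in design.y]
        self.off = np.concatenate([[0], np.cumsum(self.n_t)])
        self.n = int(self.off[-1])
        self.y = np.concatenate(design.y)
        self.X = sla.block_diag(*design.X)
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise DesignError("fixed-effect design is rank deficient")
        self.p = self.X.shape[1]
        if self.n <= self.p + 10:
            raise DesignError("too few observations for the fixed effects")
        self.var_p = float(np.mean([np.var(y, ddof=1) for y in design.y]))

        self.terms = []  # (name, q_levels, blocks {(a,b): K_ab})
        if "additive" in design.include:
            if A_inv is None:
                raise DesignError("additive term requires A_inv")
            allan = np.concatenate(design.animal)
            uniq = np.unique(allan)
            A_uu = relationship_submatrix(sp.csr_matrix(A_inv), uniq)
            code = {a: i for i, a in enumerate(uniq)}
            codes = [np.array([code[a] for a in an]) for an in design.animal]
            blocks = {(a, b): A_uu[np.ix_(codes[a], codes[b])]
                      for a in range(nt) for b in range(a, nt)}
            self.terms.append(("additive", A_inv.shape[0], blocks))
        if "litter" in design.include:
            self.terms.append(("litter",
                               len(np.unique(np.concatenate(design.litter))),
                               self._match_blocks(design.litter)))
        if "cg" in design.include:
            self.terms.append(("cg",
                               len(np.unique(np.concatenate(design.cg))),
                               self._match_blocks(design.cg)))
        res_blocks = {}
        for a in range(nt):
            for b in range(a, nt):
                if a == b:
                    res_blocks[(a, b)] = np.eye(self.n_t[a])
                else:
                    res_blocks[(a, b)] = np.equal.outer(
                        design.animal[a], design.animal[b]).astype(float)
        q_res = len(np.unique(np.concatenate(design.animal)))
        self.terms.append(("residual", q_res, res_blocks))

        # free parameters: (term index, a, b) with a <= b
        self.params = []
        for s, (name, _, _) in enumerate(self.terms):
            for a in range(nt):
                for b in range(a, nt):
                    if a != b and name in fix_cross:
                        continue
                    self.params.append((s, a, b))

    def _match_blocks(self, codes):
        nt = self.nt
        return {(a, b): np.equal.outer(codes[a], codes[b]).astype(float)
                for a in range(nt) for b in range(a, nt)}

    # -- parameter packing -------------------------------------------------
    def pack(self, mats):
        return np.array([mats[s][a, b] for s, a, b in self.params])

    def unpack(self, theta):
        mats = [np.zeros((self.nt, self.nt)) for _ in self.terms]
        for val, (s, a, b) in zip(theta, self.params):
            mats[s][a, b] = val
            mats[s][b, a] = val
        return mats

    def project(self, theta):
        """Bend every term matrix to PSD; keep the residual safely PD."""
        mats = self.unpack(theta)
        out = []
        for (name, _, _), M in zip(self.terms, mats):
            min_floor = 1e-8 * self.var_p if name == "residual" else 0.0
            out.append(_bend(M, 1.0, min_floor))
        return self.pack(out)

    def in_space(self, theta, tol=-1e-10):
        for (name, _, _), M in zip(self.terms, self.unpack(theta)):
            w = np.linalg.eigvalsh(0.5 * (M + M.T))
            lo = tol * max(1.0, abs(w).max())
            if w.min() < lo:
                return False
            if name == "residual" and w.min() <= 1e-10 * self.var_p:
                return False
        return True

    # -- likelihood ----------------------------------------------------------
    def assemble_V(self, mats):
        V = np.zeros((self.n, self.n))
        for (_, _, blocks), M in zip(self.terms, mats):
            for (a, b), K in blocks.items():
                ra, rb = slice(self.off[a], self.off[a + 1]), \
                    slice(self.off[b], self.off[b + 1])
                V[ra, rb] += M[a, b] * K
                if a != b:
                    V[rb, ra] += M[a, b] * K.T
        return V

    def loglik(self, theta, want_P=False):
        mats = self.unpack(theta)
        V = self.assemble_V(mats)
        try:
            cF = sla.cho_factor(V, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            return (-np.inf, None) if want_P else -np.inf
        logdetV = 2.0 * np.log(np.diag(cF[0])).sum()
        ViX = sla.cho_solve(cF, self.X, check_finite=False)
        Viy = sla.cho_solve(cF, self.y, check_finite=False)
        XtViX = self.X.T @ ViX
        try:
            cX = sla.cho_factor(XtViX, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            raise DesignError("X'V⁻¹X singular: fixed effects not estimable")
        logdetX = 2.0 * np.log(np.diag(cX[0])).sum()
        beta = sla.cho_solve(cX, self.X.T @ Viy, check_finite=False)
        Py = Viy - ViX @ beta
        ll = -0.5 * (logdetV + logdetX + float(self.y @ Py))
        if not want_P:
            return ll
        Vinv = sla.cho_solve(cF, np.eye(self.n), check_finite=False)
        P = Vinv - ViX @ sla.cho_solve(cX, ViX.T, check_finite=False)
        return ll, (P, Py)

    # -- per-iteration quantities ---------------------------------------------
    def derivatives(self, P, Py):
        """Gradient, AI matrix and per-term (Q, T) matrices for EM."""
        npar = len(self.params)
        grad = np.zeros(npar)
        Fmat = np.zeros((self.n, npar))
        QT = []  # per term: (Q, T) nt x nt
        tr_cache = {}
        quad_cache = {}
        for s, (_, _, blocks) in enumerate(self.terms):
            Q = np.zeros((self.nt, self.nt))
            T = np.zeros((self.nt, self.nt))
            for (a, b), K in blocks.items():
                ra = slice(self.off[a], self.off[a + 1])
                rb = slice(self.off[b], self.off[b + 1])
                t_ab = float((P[ra, rb] * K).sum())
                q_ab = float(Py[ra] @ (K @ Py[rb]))
                T[a, b] = T[b, a] = t_ab
                Q[a, b] = Q[b, a] = q_ab
                tr_cache[(s, a, b)] = t_ab
                quad_cache[(s, a, b)] = q_ab
            QT.append((Q, T))
        for k, (s, a, b) in enumerate(self.params):
            mult = 2.0 if a != b else 1.0
            grad[k] = -0.5 * mult * (tr_cache[(s, a, b)] - quad_cache[(s, a, b)])
            K = self.terms[s][2][(a, b)]
            ra = slice(self.off[a], self.off[a + 1])
            rb = slice(self.off[b], self.off[b + 1])
            Fmat[ra, k] += K @ Py[rb]
            if a != b:
                Fmat[rb, k] += K.T @ Py[ra]
        AI = 0.5 * Fmat.T @ (P @ Fmat)
        return grad, AI, QT

    def em_step(self, theta, QT):
        mats = self.unpack(theta)
        out = []
        for (name, q, _), M, (Q, T) in zip(self.terms, mats, QT):
            out.append(M + (M @ (Q - T) @ M) / q)
        return self.pack(out)

    # -- log-Cholesky transform for the AI step ------------------------------
    # Each term matrix is M = T T' with T lower triangular and
    # log-transformed diagonal, so any transformed point maps back inside
    # the PSD cone and the AI (Newton) step needs no cone constraint.

    def _term_params(self):
        """Free-parameter layout per term: list of (positions, pairs)."""
        layout = []
        k = 0
        for s in range(len(self.terms)):
            pos, pairs = [], []
            while k < len(self.params) and self.params[k][0] == s:
                pos.append(k)
                pairs.append(self.params[k][1:])
                k += 1
            layout.append((pos, pairs))
        return layout

    def to_chol(self, theta):
        xi = np.empty_like(theta)
        floor = 1e-10 * self.var_p
        for (pos, pairs), M in zip(self._term_params(), self.unpack(theta)):
            M = _bend(M, 1.0, floor)
            T = np.linalg.cholesky(M + floor * np.eye(self.nt))
            for k, (a, b) in zip(pos, pairs):
                xi[k] = np.log(T[a, a]) if a == b else T[b, a]
        return xi

    def from_chol(self, xi):
        theta = np.empty_like(xi)
        for pos, pairs in self._term_params():
            T = np.zeros((self.nt, self.nt))
            for k, (a, b) in zip(pos, pairs):
                if a == b:
                    T[a, a] = np.exp(np.clip(xi[k], -300, 300))
                else:
                    T[b, a] = xi[k]
            M = T @ T.T
            for k, (a, b) in zip(pos, pairs):
                theta[k] = M[a, b]
        return theta

    def chol_jacobian(self, xi):
        """J = d(theta)/d(xi), block diagonal over terms."""
        npar = len(self.params)
        J = np.zeros((npar, npar))
        for pos, pairs in self._term_params():
            tval = {}
            for k, (a, b) in zip(pos, pairs):
                tval[(b, a)] = np.exp(xi[k]) if a == b else xi[k]
            for krow, (a, b) in zip(pos, pairs):      # theta_k = M[a, b]
                for kcol, (c, d) in zip(pos, pairs):  # xi_k ~ T[d, c]
                    # M[a,b] = sum_j T[a,j] T[b,j]; dM/dT[d,c] =
                    # delta(a,d) T[b,c] + delta(b,d) T[a,c]
                    val = 0.0
                    if a == d:
                        val += tval.get((b, c), 0.0)
                    if b == d:
                        val += tval.get((a, c), 0.0)
                    if c == d:  # log-diagonal: chain rule dT/dxi = T
                        val *= tval.get((d, c), 0.0)
                    J[krow, kcol] = val
        return J

    def default_init(self):
        """Neutral start: residual 50% of phenotypic variance, the rest split
        equally among the other terms; covariances 10% of the geometric mean."""
        n_other = len(self.terms) - 1
        mats = []
        vp = [np.var(y, ddof=1) for y in self.design.y]
        for name, _, _ in self.terms:
            M = np.zeros((self.nt, self.nt))
            for a in range(self.nt):
                M[a, a] = 0.5 * vp[a] if name == "residual" else \
                    0.5 * vp[a] / max(n_other, 1)
            for a in range(self.nt):
                for b in range(a + 1, self.nt):
                    M[a, b] = M[b, a] = 0.1 * 0.5 * np.sqrt(M[a, a] * M[b, b])
            mats.append(M)
        return self.pack(mats)


def _reml_iterate(prob: _REMLProblem, init=None, tol=1e-8, max_iter=200):
    theta = prob.project(np.asarray(init, dtype=float)) if init is not None \
        else prob.default_init()
    scale = max(float(np.abs(theta).max()), 1e-3 * prob.var_p)
    ll, state = prob.loglik(theta, want_P=True)
    if not np.isfinite(ll):
        raise DesignError("initial covariance matrices give a singular V")
    path = [ll]
    grad = np.zeros(len(prob.params))
    AI = np.eye(len(prob.params))
    step_norm = np.inf
    converged = False
    stagnant = 0
    it = 0
    for it in range(1, max_iter + 1):
        P, Py = state
        grad, AI, QT = prob.derivatives(P, Py)
        # AI (Newton) step on the log-Cholesky scale: any step maps back
        # inside the parameter space, so near-boundary covariance matrices
        # do not stall the ascent.
        xi = prob.to_chol(theta)
        J = prob.chol_jacobian(xi)
        g_t = J.T @ grad
        AI_t = J.T @ AI @ J
        ridge = 1e-8 * max(np.abs(np.diag(AI_t)).max(), 1.0)
        try:
            dxi = np.linalg.solve(AI_t + ridge * np.eye(len(g_t)), g_t)
        except np.linalg.LinAlgError:
            dxi = g_t / max(np.abs(np.diag(AI_t)).max(), 1.0)
        big = np.abs(dxi).max()
        if big > 2.5:  # trust region on the transformed scale
            dxi *= 2.5 / big
        cand = prob.project(prob.from_chol(xi + dxi))
        # ascent guard: halve the transformed step, then fall back to EM
        # (cheap likelihood-only evaluations while searching)
        floor_ll = ll - 1e-10 * max(1.0, abs(ll))
        ll_new = prob.loglik(cand)
        n_half = 0
        while ll_new < floor_ll and n_half < 8:
            dxi *= 0.5
            cand = prob.project(prob.from_chol(xi + dxi))
            ll_new = prob.loglik(cand)
            n_half += 1
        if ll_new < floor_ll:
            cand = prob.project(prob.em_step(theta, QT))
            ll_new = prob.loglik(cand)
            n_half = 0
            while ll_new < floor_ll and n_half < 8:
                cand = prob.project(theta + 0.5 * (cand - theta))
                ll_new = prob.loglik(cand)
                n_half += 1
        if ll_new < floor_ll:
            converged = step_norm < 10 * tol  # stalled
            break
        step = cand - theta
        dll = ll_new - ll
        theta = cand
        ll, state = prob.loglik(theta, want_P=True)
        path.append(ll)
        scale = max(float(np.abs(theta).max()), 1e-3 * prob.var_p)
        rel_change = float(np.abs(step).max()) / scale
        step_norm = rel_change
        if rel_change < tol and abs(dll) < tol * max(1.0, abs(ll)):
            converged = True
            break
        # stagnation stop: the likelihood is flat to numerical precision,
        # so further iterations cannot move the estimates meaningfully
        stagnant = stagnant + 1 if abs(dll) < 1e-9 * max(1.0, abs(ll)) else 0
        if stagnant >= 3:
            converged = rel_change < 100 * tol
            break
    # sampling covariance from the final AI matrix
    try:
        cov = np.linalg.inv(AI + 1e-12 * np.eye(len(grad)))
    except np.linalg.LinAlgError:  # pragma: no cover
        cov = np.full((len(grad), len(grad)), np.nan)
    rec = ConvergenceRecord(converged=converged, iterations=it, loglik=float(ll),
                            grad_norm=float(np.linalg.norm(grad)),
                            step_norm=float(step_norm), loglik_path=path)
    if not converged:
        log.warning("REML did not converge in %d iterations", it)
    return theta, cov, rec


# ------------------------------------------------------------- public fits

def reml_fit_single(y, design: ModelDesign, A_inv=None, init=None,
                    tol=1e-8, max_iter=200) -> VarianceComponents:
    """Single-trait AI-REML. `y` overrides the response in `design` if given."""
    if design.n_traits != 1:
        raise DesignError("reml_fit_single needs a single-trait design")
    if y is not None:
        design = ModelDesign(**{**design.__dict__, "y": [np.asarray(y, float)]})
    prob = _REMLProblem(design, A_inv=A_inv)
    theta0 = None
    if init is not None:
        theta0 = [float(init[name]) for name, _, _ in prob.terms]
    theta, cov, rec = _reml_iterate(prob, init=theta0, tol=tol, max_iter=max_iter)
    names = [name for name, _, _ in prob.terms]
    comps = dict(zip(names, theta))
    se = dict(zip(names, np.sqrt(np.clip(np.diag(cov), 0, None))))
    return VarianceComponents(components=comps, se=se, cov=cov,
                              param_index={n: i for i, n in enumerate(names)},
                              convergence=rec)


def reml_fit_two_trait(y1, y2, design: ModelDesign, A_inv=None, init=None,
                       tol=1e-8, max_iter=200,
                       fix_cross=()) -> CovarianceComponents:
    """Two-trait AI-REML; `fix_cross` pins chosen terms' covariances at 0."""
    if design.n_traits != 2:
        raise DesignError("reml_fit_two_trait needs a two-trait design")
    if y1 is not None or y2 is not None:
        ys = [np.asarray(y1, float) if y1 is not None else design.y[0],
              np.asarray(y2, float) if y2 is not None else design.y[1]]
        design = ModelDesign(**{**design.__dict__, "y": ys})
    prob = _REMLProblem(design, A_inv=A_inv, fix_cross=fix_cross)
    theta0 = None
    if init is not None:
        mats = [np.asarray(init[name], float) for name, _, _ in prob.terms]
        theta0 = prob.pack(mats)
    theta, cov, rec = _reml_iterate(prob, init=theta0, tol=tol, max_iter=max_iter)
    mats = prob.unpack(theta)
    matrices = {name: M for (name, _, _), M in zip(prob.terms, mats)}
    pidx = {(prob.terms[s][0], a, b): k for k, (s, a, b) in enumerate(prob.params)}
    return CovarianceComponents(traits=list(design.traits), matrices=matrices,
                                cov=cov, param_index=pidx, convergence=rec)


# ------------------------------------------------------- derived quantities

def heritability(vc: VarianceComponents, denominator_mode: str = "all"):
    """h² = sigma2_u / total with a delta-method SE.

    mode "all" sums every estimated component into the denominator;
    "no_cg" leaves the contemporary-group variance out.
    """
    names = list(vc.param_index)
    if "additive" not in names:
        raise ValueError("no additive component in the fit")
    denom_names = [n for n in names
                   if not (denominator_mode == "no_cg" and n == "cg")]
    total = sum(vc.components[n] for n in denom_names)
    if total <= 0:
        raise ZeroDivisionError("zero phenotypic variance")
    h2 = vc.components["additive"] / total
    grad = np.zeros(len(names))
    for i, n in enumerate(names):
        d_num = 1.0 if n == "additive" else 0.0
        d_den = 1.0 if n in denom_names else 0.0
        grad[i] = (d_num * total - vc.components["additive"] * d_den) / total**2
    se = float(np.sqrt(max(grad @ vc.cov @ grad, 0.0)))
    return h2, se


def correlations(cc: CovarianceComponents):
    """Genetic correlation (delta-method SE) and component-sum phenotypic
    correlation from a two-trait fit."""
    G = cc.matrices["additive"]
    if G[0, 0] <= 0 or G[1, 1] <= 0:
        raise ZeroDivisionError("zero additive variance")
    rg = G[0, 1] / np.sqrt(G[0, 0] * G[1, 1])
    dr = {("additive", 0, 0): -rg / (2 * G[0, 0]),
          ("additive", 0, 1): 1.0 / np.sqrt(G[0, 0] * G[1, 1]),
          ("additive", 1, 1): -rg / (2 * G[1, 1])}
    grad = np.zeros(cc.cov.shape[0])
    for key, val in dr.items():
        if key in cc.param_index:
            grad[cc.param_index[key]] = val
    rg_se = float(np.sqrt(max(grad @ cc.cov @ grad, 0.0)))
    p1 = sum(M[0, 0] for M in cc.matrices.values())
    p2 = sum(M[1, 1] for M in cc.matrices.values())
    p12 = sum(M[0, 1] for M in cc.matrices.values())
    if p1 <= 0 or p2 <= 0:
        raise ZeroDivisionError("zero phenotypic variance")
    rp = p12 / np.sqrt(p1 * p2)
    return {"r_g": float(rg), "r_g_se": rg_se, "r_p": float(rp)}


def raw_phenotypic_correlation(phenotypes: pd.DataFrame, t1: str, t2: str) -> float:
    """Plain Pearson correlation of the two trait columns (paired animals)."""
    sub = phenotypes[[t1, t2]].dropna()
    return float(sub[t1].corr(sub[t2]))
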