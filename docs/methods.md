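# Methods

`penphen` estimates genetic parameters for video-derived pig behavior
traits. The pipeline has four stages — synthetic data generation,
rule-based quality control of day-wise records, per-animal trait
aggregation, and REML animal-model fitting — orchestrated by
`penphen.pipeline`. This note documents the models, the choices behind
them, and what the synthetic data do and do not emulate.

## The animal model

All fits use the linear mixed model

```
y = X b + Z u + W1 l + W2 c + e
```

where `y` holds one phenotype per animal per trait (behavior traits are
per-day averages in minutes, distance in meters; production traits ADG
g/day, back fat mm, loin depth mm measured at off-test), `b` is the fixed
line effect (corner-point coding: first line level absorbed into the
intercept; variance components are invariant to this choice), `u` is the
additive genetic effect with `Var(u) = A σ²_u` (single trait) or
`A ⊗ G` (two traits), `l` the common-litter effect (`I σ²_l` / `I ⊗ L`),
`c` the contemporary-group effect (`I σ²_c` / `I ⊗ C`, groups defined by
off-test batch), and `e` the residual (`I σ²_e` / `I ⊗ R`, with
cross-trait residual covariance only between records of the same animal).
`A` is the numerator relationship matrix; a pen or camera effect is not
fitted because it is confounded with litter in this housing design.

Derived quantities: heritability `h² = σ²_u / (σ²_u + σ²_l + σ²_c + σ²_e)`
(the contemporary-group variance is included in the denominator by
default; `denominator_mode="no_cg"` drops it), genetic correlation
`r_g = g₁₂ / √(g₁₁ g₂₂)`, and the component-sum phenotypic correlation
`r_p = (g₁₂ + l₁₂ + c₁₂ + r₁₂) / √(p₁ p₂)`. A raw-Pearson phenotypic
correlation is available as an alternative (`raw_phenotypic_correlation`);
the component-sum form is the default because it uses the same machinery
as every other reported quantity. Standard errors for `h²` and `r_g` are
delta-method transforms of the inverse average-information matrix;
no SE is attached to phenotypic correlations.

## Pedigree machinery

`build_A` uses the tabular method
(`a_ij = ½(a_{j,s(i)} + a_{j,d(i)})`, `a_ii = 1 + ½ a_{s(i),d(i)}`);
inbreeding is either `diag(A) − 1` or, above 5000 animals, a
Meuwissen–Luo style ancestor traversal with O(n) memory (the two agree to
1e-12 on random pedigrees in the suite). `build_A_inverse` applies
Henderson's rules with Mendelian-sampling variances
`d_i = 1 − ¼ Σ_p (1 + F_p)` over known parents; unknown parents are
unrelated, non-inbred base animals (no genetic groups). The REML API
takes the sparse `A⁻¹`; the dense-V engine recovers the relationship
submatrix among observed animals by sparse-LU solves on `A⁻¹`, so a dense
pedigree-wide `A` is never inverted.

## REML

`reml_fit_single` / `reml_fit_two_trait` maximize the restricted
log-likelihood of the marginal model
`V = Σ_s M_s ∘ K_s` (trait-covariance matrices `M_s` for
additive/litter/CG/residual against fixed observation-level kernels),
with dense Cholesky factorizations of `V` — appropriate for the few
thousand observations these designs produce.

Numerical choices that matter:

* **Stepping.** Average-information (Newton) steps are taken on a
  log-Cholesky parameterization of each `M_s` (`M = T T'`, log-transformed
  diagonal of `T`), so every proposal is automatically positive
  semi-definite. On the raw covariance scale the full AI step almost
  always crosses a boundary from neutral starts (a small litter/CG
  variance goes negative, or a strong genetic correlation leaves the PSD
  cone), which would force slow EM crawling. A trust region caps the
  transformed step at 2.5 per coordinate.
* **Ascent guard.** A step is accepted only if the restricted
  log-likelihood does not decrease; otherwise the transformed step is
  halved (up to 8 times), then an EM-REML step
  (`M⁺ = M + M (Q_s − T_s) M / q_s`) is tried with the same guard. The
  recorded likelihood path is non-decreasing by construction and the
  suite asserts it.
* **Bending.** Any matrix that drifts numerically outside the PSD cone is
  bent by eigenvalue flooring at `1e-8 × trace`; the residual matrix is
  kept strictly positive definite (floor `1e-8 ×` phenotypic variance) so
  `V` stays invertible even when other components sit at zero.
* **Initialization.** Residual starts at 50% of the phenotypic variance,
  the remainder split equally among the other terms; cross-covariances
  start at 10% of `½√(v₁ v₂)`. Neutral and reproducible; fits from truth
  and from the neutral start reach identical optima on the suite's
  fixtures.
* **Convergence.** Declared when the largest relative parameter change
  and the relative likelihood change both fall below `tol`
  (default `1e-8`; the recovery harness uses `1e-6`, far below the
  Monte-Carlo noise of any reported mean). The literal gradient norm is
  scale-dependent, so the step-based criterion stands in for it; the
  gradient norm is still recorded. `max_iter` defaults to 200 and
  non-converged fits are returned flagged, never silently dropped.
* **Missing data.** In two-trait fits an animal missing one trait
  contributes to the other through the standard missing-at-random
  marginal likelihood (the kernels are simply rectangular between the two
  observation sets).
* **Boundaries.** Variance components may converge to 0 (the suite checks
  that a zero-heritability truth lands at or near the boundary in ≥ 90%
  of replicates); SEs from the AI matrix are unreliable exactly at a
  boundary, as usual.

## Quality control

Four rules in fixed order, each with an audit count: (1) learning-period
removal, by calendar cutoff or recording-group tags — configurable
because equipment-calibration periods are study-specific; (2) recording
days under 8 h removed, days in [8 h, 14 h) rescaled to the 14-h
equivalent by multiplying all six behavior times and distance by
`840/minutes` (posture-sum closure and the distance/standing ratio are
invariant to this rescaling, which the suite asserts); days claiming more
than 14 h are invalid and counted separately; (3) cull-day records and
each group's first and last nominal test day removed (the nominal group
length makes the rule idempotent); (4) records whose distance exceeds
15 m per minute of standing discarded — the signature of distance
accumulating while a pig rotates sitting. The bound is strict
("exceeds"), so a record exactly at the ratio survives; standing 0 with
positive distance is removed; an optional `cap` mode truncates instead of
discarding. Exactly 8 h is kept-and-rescaled, closing the gap between
"under 8 h removed" and "8–14 h rescaled". Counts always reconcile
(`in = out + Σ removed`) and `run_qc` is idempotent.

## Aggregation

Phenotypes are unweighted per-animal means over surviving days, for the
full test and for the five sub-intervals (days 1–13, 14–26, 27–40, 41–54,
55–68 of the 70-day test; the removed boundary days 1 and 70 never fall
in an interval). Defaults require 10 surviving days for the full-period
mean and 1 per interval (configurable; the originating study does not
state a minimum). Day×day and week×week across-animal Pearson
correlation matrices use pairwise-complete observations with at least 3
pairs per cell; weeks are `7(k−1)+1 … 7k`.

## Synthetic data

The generator emulates a two-line purebred finishing study: founders plus
litters (Poisson sizes, one sire–dam pair per litter), camera/recording
groups of 19 animals, contemporary groups as off-test batches aligned
with recording groups, and 70 recording days at 14 h/day. Breeding values
follow the Mendelian-sampling recursion
`u_i = ½(u_s + u_d) + m_i`, `Var(m_i) = (1 − ¼Σ_p(1+F_p)) G`, so
`Var(u) = A ⊗ G` in expectation; litter, contemporary-group and residual
effects are i.i.d. across their levels with covariances `L`, `C`, `R`.

Two modes. `animal_level` emits one model-scale phenotype per animal —
the exact target for variance-component recovery (day averaging would
fold day noise into the effective residual). `day_level` adds per-day
structure: centred linear/quadratic age trends (eating, standing and
distance decline with age, lying rises, drinking is flat), AR(1) day
noise, zero-flooring of times and distances, posture-sum closure (the
four postures rescaled to sum exactly to recording time), and the defects
QC must catch: short recording days (uniform hours in a configurable
range), cull days (records stop, the cull day is flagged), sitting-rotation
distance artifacts (distance pushed strictly above the 15 m/min bound —
genuine movement is capped at that physical bound so defect-free data
pass QC), and early learning-period groups whose dates precede the
non-learning groups.

Default calibration: trait means and SDs match published summary
statistics for this recording design (e.g. eating 56.4 ± 19.6 min/day,
distance 872 ± 357 m/day, ADG 711 ± 64 g/day); additive fractions per
trait follow the published heritability estimates; litter and
contemporary-group fractions default to 0.05 of phenotypic variance each
(not reported in the source material; configurable); in day-level mode
40% of the daily variance is within-animal day noise. Zero-flooring
affects ~2–3% of values under these defaults, concentrated in the
short-duration traits (sitting, drinking) that genuinely pile up at zero;
the realized rate is reported per run. The default cross-trait
covariances are zero — pairwise analyses set `G`/`R` correlations
explicitly (`pipeline.recovery_config` solves the residual
cross-covariance so a requested total phenotypic correlation holds).

What passing tests do *not* show about real data: the generator draws
every effect from the stated Gaussian model, so it cannot reveal model
misspecification (non-normal behavior distributions, genotype-by-
environment effects, seasonal lying patterns, heterogeneous day-noise),
identification drop-outs from ear-tag reading, or selection in the
pedigree. Recovery results certify the estimation machinery, not the
biology.

## Recovery experiments and problem sizes

`recovery_experiment` repeats simulate→fit and reports per-parameter
mean, empirical SD, bias, mean delta-method SE and 95% coverage. The
headline harness (also used by `scripts/acceptance.py`) simulates
pedigrees of ~1000 animals — 200 founders and two generations of 50
litters of mean size 8 — phenotypes the 800 non-founders (founders have
no litter of their own; including them would add singleton litters and
distort the litter-variance structure), assigns 20 contemporary groups,
sets phenotypic variance to 1 with litter and CG fractions 0.05, and runs
20 replicates per target at REML tolerance 1e-6. At these sizes a
single-trait fit takes well under a second and a bivariate fit a few
seconds. Genetic-correlation estimates near ±1 carry a small upward
finite-sample bias (~0.01 at a truth of 0.93 in this design), a known
property of the ratio estimator; correlations involving a low-h² trait
have per-replicate SDs around 0.2–0.3, so 20-replicate means retain
Monte-Carlo noise of ~0.05.

## Known limitations

* Dense-V REML scales cubically; beyond ~10⁴ observations a sparse
  mixed-model-equations formulation would be needed.
* No genomic relationships, genetic groups, or repeated-records
  (permanent-environment) models.
* Phenotypic-correlation SEs are not computed.
* The generator's contemporary groups align with recording groups by
  construction; fully crossed CG×litter designs must be supplied as data.
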