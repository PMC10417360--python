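# Methods

## The estimation problem

Selection against boar taint happens in a purebred (PB) nucleus, but
the commercial traits it might damage are expressed in crossbred (CB)
slaughter pigs.  The quantity of interest is therefore the *genetic*
correlation between a boar-taint compound concentration measured on PB
young boars and a carcass or ham-quality trait measured on CB half-sibs
— two trait sets recorded on disjoint animals, linked only through the
pedigree (nucleus boars with offspring in both tiers).  The package
implements the standard solution: a bivariate pedigree-based animal
model fitted by Gibbs sampling, with the residual covariance of
disjointly recorded pairs fixed at zero, so that all cross-trait
information flows through the additive-genetic covariance `G`.

## Model and full conditionals

Per trait `t`: `y_t = X_t b_t + Z_t a_t + e_t`, with
`(a_1, a_2) ~ N(0, G ⊗ A)` over all pedigree animals and per-animal
residual covariance `R` on the recorded cells.  Priors are flat
(bounded-improper) on `b`, `G` and `R`.  One Gibbs cycle:

1. **Location parameters** `(b_1, b_2, a_1, a_2)` jointly from their
   multivariate-normal full conditional, i.e. the mixed-model equations
   `C θ = W'R⁻¹y` with `C = W'R⁻¹W + blockdiag(0, G⁻¹ ⊗ A⁻¹)`.
2. **Genetic covariance** `G` from an inverse-Wishart with scale
   `S_a[i,j] = a_i' A⁻¹ a_j` and df `q − 3` (see below).
3. **Residuals**: disjoint recording — each variance from a scaled
   inverse-chi-square (scale `e_t'e_t`, df `n_t − 2`), covariance set to
   exactly 0; joint recording — a 2×2 inverse-Wishart over the jointly
   recorded animals' residual cross-products (df `n_joint − 3`).

Derived draws `h²_t = G_tt/(G_tt + R_tt)` and
`r_g = G₁₂/√(G₁₁G₂₂)` are stored per retained iteration.

### Degrees-of-freedom convention

With a constant prior, completing the inverse-Wishart kernel for `p = 2`
traits gives df `q − 3` (genetic) and `n − 3` / `χ²_{n−2}` (residual).
Some samplers instead use df `q` / `n`, which is equivalent to an extra
`|G|^{-3/2}` prior factor.  That factor diverges as `G` approaches
singularity, and in repeated simulations at moderate information
(hundreds of records) it visibly attracts the chain to the `|r_g| = 1`
boundary: in 12 half-sib replicates (40 sires × 15 progeny) the 95% HPD
covered the true `r_g` only 5/12 times under df `q` versus 10/12 under
df `q − 3`, with several chains collapsing to a point mass at ±1.  The
package therefore defaults to the flat-prior-exact convention
(`df_convention="flat"`); `df_convention="q"` switches to the other
convention, whose difference is `O(1/q)` once data dominate.

### Exact joint location draws at Gibbs speed

The location draw uses *sampling by perturbation*: with
`η = W'R⁻¹(y + e*) + F z`, where `e*` is a fresh residual draw per
record pattern and `F F' = G⁻¹ ⊗ A⁻¹`, the solution of `C θ = η` is an
exact draw from the full conditional (mean `C⁻¹W'R⁻¹y`, covariance
`C⁻¹`).  The pedigree factorization `A⁻¹ = (I−P)' D⁻¹ (I−P)` (P = half
at parent positions, D = Mendelian-sampling variances) makes `F z` an
`O(q)` operation.

`C` changes numerically every iteration but never structurally, so the
solver is a sparse Cholesky whose elimination tree and factor pattern
are computed once per run (up-looking CSparse scheme, numba kernels)
and refactorized per iteration.  Equations are ordered youngest animal
first with the two traits of an animal adjacent and fixed effects last
— on pedigree problems this keeps fill near the minimum a general
ordering would find, while skipping the per-call ordering/symbolic cost
of library LU routines (~3–13 ms versus ~64 ms per iteration at the
two-tier scale of ~9,300 equations).  Correctness is tested against a
dense full-conditional oracle (mean within Monte-Carlo error,
covariance within <1% relative) and by `A⁻¹`-identity and conjugate-
moment checks.

Numerical safeguards: a failed factorization jitters the diagonal by
`1e-8 · tr(C)/dim` once, then aborts the iteration (a run fails if >1%
of iterations abort); singular inverse-Wishart scale matrices (possible
at an all-zero start or at the correlation boundary) are ridged by
`1e-10 · tr(S)`; non-positive-definite covariance draws are redrawn (at
most 100 attempts).

## Chain presets and summaries

`ChainConfig.full()` is the full-length preset (1,000,000 iterations,
100,000 burn-in, lag 20); `ChainConfig.desk()` (20,000 / 4,000 / 4,
the default) retains 4,000 draws and is used throughout the tests and
the acceptance script.  Point estimates are posterior medians
(lower-middle order statistic for even n).  Interval estimates are
empirical shortest-window HPDs: the narrowest interval whose endpoints
are `⌈0.95·n⌉` order statistics apart, leftmost on ties.  `P₀`/`P₀₁`
count samples strictly beyond 0 / 0.1 in the direction of the median;
a correlation is flagged *different from zero* when `P₀ > 0.80` and
*relevant* when `P₀₁ > 0.70` (strict inequalities — at 4,000 retained
draws ties carry negligible mass).  The Raftery–Lewis diagnostic
(defaults q=0.025, r=0.005, s=0.95; `n_min = 3746`) is advisory: the
pipeline warns, never fails, when a dependence factor exceeds 5.

## What the generator emulates

`simulate.SimConfig` reproduces the two-tier design at any scale:
nucleus boars × nucleus sows → PB offspring with a boar-taint trait
(assay-batch fixed effect); a sire pool (the shared nucleus boars plus
unrelated extra sires) × unrelated CB dams → CB offspring with a
carcass/ham trait (sex + slaughter-group fixed effects).  Defaults are
the source population's counts (27 boars, 226 sows, 1115 PB; 731
sires, 1885 dams, 26,577 CB; 27 shared sires); `SimConfig.desk()` is
the reduced recovery scale (1000 PB, 3000 CB, all 27 nucleus boars
shared, sire/dam loads kept at full-scale ratios).  Structure scales
with realistic batch sizes — ~12 PB per assay batch and ~70 CB per
slaughter group, which at full scale reproduces the recorded 94 batch
levels and the 100–400 slaughter-group range.

Trait calibrations (`DEFAULT_TRAITS`) carry each trait's observed mean,
phenotypic SD and heritability; `DEFAULT_GENETIC_CORRELATIONS` holds
the published posterior-median correlations, so recovery tests double as
a reproduction of that parameter set.  Variances are decomposed as
`σ²_P = σ²_batch + σ²_a + σ²_e` with batch SD = 0.3 σ_P (PB) and
group SD = 0.2 σ_P plus a fixed sex contrast of 0.25 σ_P (CB), and
`h² = σ²_a/(σ²_a+σ²_e)` applied to the net model variance; the
simulated phenotypic SD then matches the calibration SD.  Breeding
values follow the exact pedigree recursion (founders `N(0, G)`;
non-founders parent-average plus Mendelian deviation with covariance
`0.5(1−(f_s+f_d)/2) G`), so their covariance is `G ⊗ A` by
construction.

Not emulated: measurement-error structure of the assays, litter/dam
nesting and maternal effects for CB pigs, selection or culling over
time, and genotypes.  Passing recovery tests therefore demonstrates
correctness of the estimation machinery under the fitted model's own
assumptions, not robustness to these real-data complications.

## Problem sizes used in the shipped checks

Chosen so the full suite and the acceptance script each run in minutes
on one CPU:

* pedigree oracle equivalence: 100 random pedigrees of 20–500 animals;
* conjugate moments: 1e5 draws per sampler;
* half-sib cross-validation: 100 sires × 20 progeny, desk preset,
  posterior median h² within 0.05 of the sire-component ANOVA;
* two-tier recovery (test suite): 500 PB / 1500 CB, 10,000 iterations —
  truths inside every 95% HPD; the acceptance script runs the full
  recovery protocol at 1000 PB / 3000 CB with the desk preset;
* HPD calibration: 50 half-sib replicates (25 sires × 30 progeny,
  true r_g = 0.5), 8,000 iterations each — 48/50 intervals covered the
  truth in the reference run (nominal 95%, binomial band 44–50);
* generator calibration: one simulated PB cohort of 1,115.

## Known limitations

* With joint recording and `R` free, animals recorded for only one of
  the two traits contribute to `R` only through their marginal variance
  weight in the location step, not the inverse-Wishart scale; the
  update is exact when recorded animals carry both traits (the usual
  same-tier situation).
* Strictly bivariate; no REML mode; no genetic groups, dominance or
  genomic relationships.
* At very weak information (few dozen families) any flat-prior
  bivariate Gibbs sampler of this type mixes slowly in `r_g` and the
  posterior itself accumulates mass near ±1; conclusions at such scales
  need the long preset and the Raftery–Lewis report should be heeded.
* The empirical HPD's endpoints carry `O(n^{-1/2})` selection noise;
  with 4,000 retained draws this is ~0.01–0.03 on a correlation.
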