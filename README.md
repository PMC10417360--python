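# gibbsam

Bayesian bivariate animal-model analysis for **boar-taint genetics in a
two-tier pig breeding design**: boar-taint compound concentrations
(androstenone, skatole, indole; log ng/g) are recorded on purebred (PB)
young boars in a nucleus, while carcass and ham-quality traits are
recorded on crossbred (CB) half-sibs in a sib-testing program.  The
package estimates heritabilities and the genetic correlations between
the PB and CB trait groups — the quantities a breeder needs before
selecting against boar taint — together with a synthetic-data generator
that reproduces the population design, so every stage of the analysis
is testable without access to restricted industry data.

## Model

For a trait pair (one boar-taint trait, one production/ham trait):

    y_t = X_t b_t + Z_t a_t + e_t,          t = 1, 2
    (a_1, a_2) ~ N(0, G ⊗ A),   (e_1, e_2) ~ N(0, R) per animal

* `A` — numerator relationship matrix from the pedigree (its sparse
  inverse is built by Henderson's rules with inbreeding from the
  Meuwissen–Luo recursion),
* `b_t` — systematic effects (assay batch for boar-taint traits; sex
  and slaughter group for crossbred traits), flat priors,
* `G`, `R` — genetic and residual 2×2 covariance matrices, flat priors.
  Because no animal carries both a PB and a CB record, the residual
  covariance of such pairs is not estimable and is **constrained to
  exactly zero**; the genetic correlation is then identified purely
  through the pedigree connections (sires with offspring in both tiers).

A Gibbs sampler cycles: a joint multivariate-normal draw of all
location parameters through the sparse mixed-model equations, an
inverse-Wishart draw of `G` (scale `a_i' A⁻¹ a_j`), and scaled
inverse-chi-square / inverse-Wishart draws of `R`.  Retained thinned
samples yield posterior medians, shortest 95% highest-posterior-density
(HPD) intervals, heritabilities `h² = σ²_a/(σ²_a+σ²_e)`, genetic
correlations `r_g = G₁₂/√(G₁₁G₂₂)`, the sign probabilities `P₀`/`P₀₁`
(posterior probability the correlation exceeds 0 / 0.1 in the direction
of its point estimate) and the associated decision flags
(`P₀ > 0.80` → different from zero, `P₀₁ > 0.70` → relevant).
Chain convergence is assessed with the Raftery–Lewis run-length
diagnostic.

## Worked example

```python
from gibbsam import (SimConfig, simulate, BivariateModelSpec, TraitModel,
                     build_design, ChainConfig, run_chain, summarize)

# two-tier data: log-skatole on ~1000 purebreds, backfat on ~3000
# crossbreds, 27 nucleus boars siring offspring in both tiers,
# true h2 = 0.49 / 0.41 and true genetic correlation -0.55
cfg = SimConfig.desk("skatole", "backfat", seed=1)
sim = simulate(cfg)

spec = BivariateModelSpec(
    TraitModel("skatole", ("date_of_analysis",)),
    TraitModel("backfat", ("sex", "slaughter_group")))
design = build_design(sim.ped, sim.phenotypes, spec)

store = run_chain(design, ChainConfig.desk(seed=1001))
print(summarize(store).to_string(index=False))
```

Output (abridged; the run takes a couple of minutes):

```
parameter  median  hpd_low  hpd_high      p0     p01  nonzero  relevant
      G11  0.5119   0.3223    0.7204  1.0000  1.0000     True      True
      R12  0.0000   0.0000    0.0000  0.0000  0.0000    False     False
    h2_t1  0.5058   0.3655    0.6853  1.0000  1.0000     True      True
    h2_t2  0.4262   0.3429    0.5043  1.0000  1.0000     True      True
       rg -0.3191  -0.6875    0.1251  0.9125  0.8430     True      True
```

Reading: the heritability of log-skatole is recovered at 0.51 (truth
0.49), backfat at 0.43 (truth 0.41); the genetic correlation posterior
is centred at -0.32 with a wide HPD covering the simulation truth
-0.55 -- wide because only 27 sires connect the two tiers, exactly as
in the real design.  `R12` is identically zero: the structural
constraint for disjointly recorded pairs.

The same workflow is available from the shell:

```bash
gibbsam simulate -c config.yaml -o data/ --seed 1
gibbsam fit -p data/pedigree.csv -f data/phenotypes.csv \
        --trait1 skatole --trait2 backfat --seed 2 -o samples.csv
gibbsam summarize samples.csv
gibbsam diagnose samples.csv --plot traces.png
gibbsam study -p data/pedigree.csv -f data/phenotypes.csv -c study.yaml -o out/
```

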