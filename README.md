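# voleherit

Quantitative-genetic analysis of social behaviour in pedigreed vole
colonies: how much of the variation in pair bonding, aggression,
parental care and brain vasopressin-receptor (V1aR) density is
heritable, and how much is environmental plasticity?

The package is built for analyses of closed laboratory colonies of
socially monogamous rodents (prairie voles, *Microtus ochrogaster*, are
the motivating system) in which focal males are tested with a partner
and a stranger female, and relatedness among all animals is known from
the colony pedigree. It provides:

* **Pedigrees and relationship matrices** — validation, topological
  sorting, and the additive (numerator) relationship matrix **A** built
  by the tabular method, with its dense inverse.
* **A Bayesian animal model with indirect genetic effects** — the mixed
  model

  ```
  y = 1β + Z_m m + Z_p p + Z_s s + e
  m ~ N(0, A σ²_m),  p ~ N(0, A σ²_p),  s ~ N(0, A σ²_s),  e ~ N(0, I σ²_e)
  ```

  where `m` is the focal male's additive genetic effect and `p`, `s` are
  *indirect* genetic effects — contributions of the partner's and
  stranger's genotypes to the focal male's phenotype. Variance
  components are estimated by Gibbs sampling with conjugate full
  conditionals; narrow-sense heritability of each effect is its
  per-draw share of σ²_m + σ²_p + σ²_s + σ²_e, summarised by the
  posterior mean ± SD. A parent–offspring regression estimator
  (h² = 2 × slope) is included as a cross-check.
* **Synthetic colonies with known truth** — a generator for the block
  crossing design (full-sib founder males × unrelated full-sib females,
  bred forward with fresh unrelated females each generation) and
  phenotypes drawn from the generative model, retaining every hidden
  effect for parameter-recovery scoring.
* **Behavioural statistics** — paired before/after-mating t-tests with
  Bonferroni family-wise control, partner-preference distribution
  summaries, and the Spearman rank-correlation screen of behaviours
  against per-section V1aR optical densities (exact permutation
  P-values at n ≤ 7).

## Worked example

Simulate a study-scale colony (416 pedigree animals, 182 phenotyped
males), generate a trait with true focal-male heritability 0.5, and fit
the three-effect animal model with the desk-speed chain:

```python
import voleherit as vh

pedigree = vh.generate_colony_pedigree()          # 13 blocks, 2 generations
A = vh.additive_relationship_matrix(pedigree)
triples = vh.assign_partners_strangers(pedigree, seed=11, A=A)
truth = vh.VarianceTruth.from_heritability(0.5, beta=59.0, total=4.0)
dataset = vh.simulate_phenotypes(pedigree, triples, truth, seed=12, A=A)

model = vh.AnimalModel.from_trials(dataset.trials, A)
results = model.fit(vh.GibbsConfig.fast(seed=13))
print(results.summary())
```

```
Animal model (Gibbs sampler)
==========================================================
trials: 182   animals in A: 416
effects: male, partner, stranger
chain: 28000 iterations, burn-in 3000, thin 25 -> 1000 retained (seed 13)
----------------------------------------------------------
parameter     post. mean    post. SD       ESS
beta             59.0129      0.2365      1000
var_male          1.4845      0.6621       246
var_partner       0.0995      0.1528        33
var_stranger      0.0684      0.1222        24
var_e             2.3446      0.5515       208
----------------------------------------------------------
h2_male           0.3656      0.1379
h2_partner        0.0247      0.0375
h2_stranger       0.0170      0.0301
==========================================================
```

The intercept is recovered almost exactly (59.01 vs the true 59), and
the focal-male heritability posterior (0.37 ± 0.14) covers the true 0.5
within one posterior SD — with ~180 single-record males the posterior
is honest about how little a colony of this size can pin down a
variance ratio. The low effective sample sizes for the partner and
stranger variances flag the components the data barely inform; the
production schedule (`GibbsConfig.production()`: 280,000 iterations, 30,000
burn-in, thin 25, 10,000 retained draws) is recommended for reported
estimates.

The same objects drive the command line:

```bash
voleherit simulate --out sim/                 # colony + phenotypes + truth
voleherit fit --pedigree sim/pedigree.csv --trials sim/trials.csv \
              --chain-preset fast --out fit/
voleherit recover --chain-preset fast --out recovery/
voleherit screen --behaviours behaviours.csv --densities densities.csv --out screen/
```

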