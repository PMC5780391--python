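# Methods

## The model

One trial records the seconds a focal male spends on a behaviour (or an
optical-density reading for receptor traits) together with the
identities of the male, his partner female and the stranger female.
The observation model is

    y = 1β + Z_m m + Z_p p + Z_s s + e,

with a single systematic effect (the intercept β, flat prior), three
additive genetic effect vectors indexed over the *whole* pedigree —
`m` for the focal male (direct effect), `p` and `s` for the partner and
stranger females (indirect genetic effects: the contribution a social
partner's genotype makes to the focal animal's phenotype) — and
i.i.d. residuals. Each effect vector is a priori N(0, **A** σ²) with
**A** the numerator relationship matrix, so relatives have correlated
effects; residual covariance is **I** σ²_e (trials are independent given
the effects). Narrow-sense heritability of each component is its share
of the total σ²_m + σ²_p + σ²_s + σ²_e.

Key assumptions: additive gene action only (no dominance/epistasis or
maternal-effect terms), one record per male per trait, no fixed effects
beyond the intercept, and untransformed trait values (an optional
z-scoring flag exists; variance *ratios* are scale-free, so it changes
nothing but the units of the variance draws).

## Relationship matrix

**A** is built by the tabular method over a topologically sorted
pedigree: `a_ii = 1 + 0.5 a_sd` and `a_ij = 0.5 (a_js + a_jd)`, with
unknown parents contributing zero. Unknown parents are treated as
unrelated, non-inbred founders; animals appearing only on the parent
side are auto-inserted as founders with a warning. Inbred loops (e.g.
full-sib matings) are handled by the same recursion and show up as
diagonal entries above 1. At colony scale (hundreds of animals) dense
linear algebra is exact and cheap, so the inverse needed by the sampler
is a dense Cholesky solve rather than Henderson's sparse rules; the
test suite cross-checks the tabular build against an independently
coded recursive-coancestry oracle to 1e-12.

## Gibbs sampler

Full conditionals are all conjugate:

* β — normal, mean the average residual excluding β, variance σ²_e/n;
* each effect vector — one multivariate-normal *block* draw with
  precision `Z'Z/σ²_e + A⁻¹/σ²_x` (block updates mix far better than
  single-site updates at a few hundred animals);
* each genetic variance — scaled-inverse-χ² with degrees `q + ν₀` and
  scale `(u'A⁻¹u + ν₀S₀)/(q + ν₀)`, where q is the pedigree size;
* σ²_e — the same form from the residual sum of squares with degrees
  `n + ν₀`.

Because each trial touches exactly one animal per effect, `Z'Z` is
diagonal and fixed, so the pair `(Z'Z, A⁻¹)` is simultaneously
diagonalised once per fit by a generalised eigendecomposition; each
block draw afterwards costs two matrix–vector products and the
quadratic form `u'A⁻¹u` is free in the rotated basis. This makes the
production schedule (280,000 iterations, 30,000 burn-in, thin 25 —
10,000 retained draws) run in about a minute and a half for a
416-animal colony on one CPU; a desk-speed preset (28,000/3,000/25)
exists for exploratory fits and tests.

Priors are a deliberate choice, since weak scaled-inverse-χ² priors are
the standard near-noninformative-but-proper default for variance
components: ν₀ = 0.002, S₀ = 1 per component, configurable. The
intercept prior is flat. Chains are deterministic given the seed.
Divergent (non-finite) variance draws raise an error naming the
iteration rather than silently continuing.

Heritability is computed **per retained draw** and then averaged
(mean of ratios, the standard posterior functional for a derived
parameter), with the across-draw SD reported as the standard error;
the per-draw shares plus the residual share sum to one exactly.

Model variants: the partner and stranger terms are optional. Traits
measured without social context (receptor densities) degrade gracefully
to a male-effect-only model, and with all genetic terms disabled the
sampler reduces to the conjugate intercept+residual model, whose
marginal posterior for σ²_e is known in closed form — the test suite
exploits this as an exact check.

## Diagnostics

Effective sample size uses Geyer's initial-positive-sequence estimator
(autocorrelations summed over consecutive pairs while the pair sums
remain positive); the output names the estimator. A constant chain has
no defined ESS and is flagged rather than raised. Lag-k
autocorrelations accompany every parameter for trace inspection, and
`AnimalModelResults.plot_trace` renders the retained draws.

## Parent–offspring regression

The cross-check estimator regresses male offspring phenotype on sire
phenotype, one sire–son pair per observation (offspring of the same
sire are not averaged; with at most a few sons per sire the efficiency
loss is negligible). h² = 2 × slope for single-parent regression, with
SE twice the slope's SE. Estimates outside [0, 1] are reported as-is
and flagged, not truncated.

## Synthetic colonies

The generator emulates a closed-colony crossing design: per founder
block, two full-sib males (sharing a recorded founder pair as parents)
are each mated to one of two unrelated full-sib females; each later
generation, every pairing produces a litter (sexes alternating), and
the first male of each litter is mated to a female from a fresh,
unrelated founder sib-pair. Defaults — 13 blocks, 2 bred generations,
litters of five — give 416 pedigree animals with 182 phenotyped males
(all males with recorded parents), close to the motivating design of a
~368-animal colony with 180 tested males; block count and litter size
are free parameters because only the colony totals, not the litter
arithmetic, are pinned down by the design being emulated. Partner and
stranger females are assigned to each male under the constraint
a(male, female) = 0, mirroring pairing with unrelated females.

Phenotypes are generated by the same equation the model fits: breeding
values are drawn as √σ² · L z with L the Cholesky factor of **A**, so
realised relatedness (full sibs 0.5, parent–offspring 0.5) is exact by
construction, and every hidden component is stored so recovery can be
scored against truth. For the recovery experiments the truth grid sets
the focal-male heritability to {0, 0.5, 0.8} at total variance 4 and
intercept 59 (a partner-preference-like scale in minutes), with partner
and stranger variances at zero.

What the generator does *not* emulate: behavioural time series, assay
floor/ceiling artefacts, mortality censoring, shared-cage environmental
covariance, or genotype×environment interaction. Passing recovery
therefore shows the estimator is correct *under its own model*, not
that real behavioural data meet that model. The auxiliary behavioural
and density tables (for the screening statistics) are plain
truncated-normal draws anchored to the motivating population's means
and SEs; they exercise table shapes and calibration, not biology.

## Recovery, and what "close to truth" can mean at this scale

With ~180 single-record males in a 13-block pedigree, the information
about a variance ratio is limited: an exact maximum-likelihood oracle
(dense multivariate-normal evaluation over an h² grid) shows the
dataset-to-dataset SD of the best estimate is ≈ 0.06 at true h² = 0,
≈ 0.13 at 0.5, ≈ 0.10 at 0.8. A single replicate therefore cannot be
guaranteed to land within 0.15 of truth by *any* correct estimator.
The recovery experiment accordingly simulates several colonies per
truth (5 replicates by default) and scores the replicate-averaged
posterior mean, which recovers 0, 0.5 and 0.8 comfortably within 0.15
and reproduces the qualitative contrast the design was built to detect:
near-zero heritability for behaviour-like traits versus high
heritability for receptor-density-like traits.

## Behavioural statistics

* Paired before/after comparisons use the classic paired t on
  per-animal differences (after − before; the sign convention is stated
  in the output). Animals missing one phase are excluded with a counted
  warning. The Bonferroni family size is explicit configuration
  (13 for the standard behaviour family), never inferred silently.
  The binary/frequency alloparental-aggression score is analysed by
  paired t like the rest of the family for comparability; a McNemar
  option would be the orthodox alternative and is deliberately out of
  scope.
* Spearman correlations use average ranks for ties; P-values are exact
  by full enumeration of all n! permutations for n ≤ 7 and use the
  t-approximation above that. Constant vectors yield missing (never
  flagged) results. The screen's multiplicity divisor is configuration,
  defaulting to the number of correlations actually computed.
* The partner-preference summary reports mean, SE (= SD/√n), extrema
  and histogram counts over 10-minute bins spanning the three-hour
  test; counts always conserve n.
* Two-sided P-values throughout.

## Numerical choices

* Pedigree CSV dialect: comma-separated with header `animal,sire,dam`
  (optional `generation,sex`); empty or `"0"` parent fields mean
  unknown. `0` remains a valid *generation* value.
* Non-positive-definite relationship matrices raise with a condition
  estimate; the sampler refuses rather than regularises.
* The generalised eigendecomposition clips tiny negative eigenvalues of
  `Z'Z` (they are exact zeros in exact arithmetic) at zero.
* Effect draws use one multivariate draw per effect per iteration;
  tie-breaking in the topological sort is stable, so already-sorted
  pedigrees round-trip unchanged.
* Seeds are always explicit arguments; derived child seeds come from
  `numpy.random.SeedSequence` spawn keys and stay below 2³¹.

## Limitations

Single-trait analyses only: no genetic correlations between traits, no
multivariate animal model, no REML alternative, no dominance or
maternal components. The Spearman screen's family size and the exact
divisor behind externally reported thresholds (e.g. 7.5 × 10⁻⁵-style
corrected levels) are user configuration, because such divisors depend
on how many behaviour × section contrasts a given study counted. Fits
assume the pedigree is complete and correct; genotype-based (marker)
relatedness is out of scope.
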