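# Methods

`ecotensor` implements a quantitative-genetic analysis of what hybrid
breakdown removes from a set of locally adapted ecotypes: multivariate
phenotypic divergence, Bayesian models of binary field fitness, and a
covariance-tensor comparison of among-habitat fitness matrices across
hybrid generations. A synthetic-data module generates the full crossing
design and field experiment so that every stage runs, and can be validated,
without external data. This note records the models, the choices that were
genuinely open, and what the synthetic data do and do not establish.

## The study system being emulated

Four ecotypes of a self-incompatible wildflower, each native to one of four
habitats (sand dune, rocky headland, subtropical tableland, dry woodland),
are crossed to produce reciprocal F1 hybrids, F2s carrying one grandparent
from every ecotype, three replicate F2→F3 lines, and a paired full-sib /
half-sib F4 generation. The F2 generation suffers a fertility crash
(reduced seed set) that recovers by F3 — the signature of
Bateson–Dobzhansky–Muller (BDM) incompatibilities among derived alleles.
Seeds of the parental, F1 and F4 generations are transplanted into all four
habitats and scored for three binary fitness components: emergence,
establishment (reaching 10 leaves) and maturity (producing a bud).

## Synthetic data generator (`synthdata`)

**Pedigree.** Ordered ecotype pairs give 12 F1 cross types; matings between
F1 types with disjoint ecotype pairs give 24 ordered F2 cross-type
combinations, so every F2 carries all four grandparental ecotypes. F2
families are partitioned round-robin into three replicate lines; F3s come
from random within-line matings; F4 families from a paired sire/dam design
in which each sire is mated to two dams and dams may serve two sires.
Default counts follow the design that motivated the package (41–60 base
parents per ecotype scaled to 48, 20–25 F1 and 17–22 F2 families per cross
type, ≈259 F3 and ≈198 F4 families).

**Genetic architecture of incompatibility.** One unlinked biallelic locus
per ecotype carries that ecotype's derived dominant allele; founders are
homozygous at their own locus only, and transmission is Mendelian. For a
cross, every between-ecotype locus pair contributes a multiplicative
seed-set retention factor: hom × hom interactions are unpenalized, hom ×
het and het × het interactions carry configurable penalties in [0, 1].
Seed counts are Poisson around `baseline_seed_mean` times the retention
product; a cross succeeds when it yields ≥ 2 seeds. A disjoint F1 × F1
mating exposes exactly four het × het pairs, so the default het × het
penalty `1 − 0.51^(1/4)` produces a 49% F2 seed-set reduction relative to
F1. Four loci is the minimal architecture covering all pairwise
between-ecotype interactions; two-locus cartoons generalize to it directly.

**Traits.** Seven glasshouse traits (height plus six leaf-shape variables).
Parental expectations are ecotype mean vectors; hybrid expectations are
ancestry-weighted means (additive baseline) with an optional dominance
offset scaled by expected heterozygosity. Family and residual deviations
are iid normal. When `between_ecotype_cov` (B) is supplied, the realized
ecotype means are drawn from N(row of `trait_means`, B), which makes B the
estimand of the divergence matrix D — the property the estimator-recovery
tests exercise. The default fixed means put the four ecotypes mostly along
one dominant axis (tableland vs headland) with a weaker second axis
(woodland vs tableland), giving a strongly one-dimensional D as in highly
divergent radiations.

**Field fitness.** Establishment is governed by a latent logit-scale score:
habitat intercept + native advantage δ_h (parental ecotype at home) +
heterosis (latent shifts for F1 and F4) + a genotype effect + family and
block effects + a standard logistic residual. The genotype effect is a
4-vector over habitats drawn per cross type (parents: 4 populations; F1:
6 unordered cross types) or per family (F4) from that generation's 4×4
covariance — the character-state truth V_P, V_F1, V_F4. Defaults encode
the pattern the analysis is designed to detect: strong negative
among-habitat correlations and large variance for parents (r = −0.30,
variances 1.44), weaker negative for F1 (r = −0.15, variances 1.0),
positive correlations and reduced variance for F4 (r = +0.50, variances
0.12–0.56, smallest where native advantage is largest).

The three binary outcomes threshold one shared logistic residual at
stage-shifted cutoffs (emergence shifted up, maturity shifted down). This
comonotone coupling guarantees emergence ≥ establishment ≥ maturity row by
row while keeping each stage's marginal probability exactly
logit⁻¹(linear predictor + shift); it overstates the within-seed
correlation of stages, which none of the analyses consume.

**Coupling F4 variance to realized adaptation.** Realized per-habitat
adaptation strength (native minus mean foreign) includes the parental
genotype draws, whose latent SD (≈1.4) exceeds the spread of the
configured δ_h. If the F4 covariance were fixed at its configured value,
the association "stronger adaptation → lower F4 variance" would hold only
on average, not replicate by replicate. The generator therefore damps the
F4 family variance in each habitat by `exp(−c · excess)`, where `excess`
is the realized minus configured native advantage on the latent scale and
c = `f4_adaptation_coupling` (default 1.0; the log-damping is clipped at
±1.2 so damped variances remain identifiable from binary data). This makes
the association structural — selection removed more variance where
adaptation was in fact stronger, the mechanism under study — while
preserving the configured F4 correlation structure. `truth.json` records
the effective matrix; setting the coupling to 0 restores the configured
matrix as the exact truth (used by the covariance-recovery tests).

**What the generator does not emulate.** No linkage or genetic maps, no
spatial arrangement of field blocks, no germination-time dynamics, no
cytoplasmic effects, no selection during the crossing programme itself
(F3 "recovery" is implicit: F3/F4 fitness truths are configured, not
evolved). Passing tests therefore show that the estimators recover the
structures the generator plants, not that real data satisfy the
generator's assumptions.

## Phenotypic divergence (`phenodiv`)

Traits are standardized (mean 0, SD 1) pooled over whatever rows are passed
in — the intended pool is parentals plus F4 together, so both the pairwise
and four-ecotype analyses share one scale. One-way MANOVA partitions the
total centered SSCP into hypothesis (between-group) and error matrices;
Wilks' λ = det(E)/det(E+H) is tested with Rao's F transformation (exact
for ≤2 groups or ≤2 traits) and a Bonferroni-corrected α (0.05/number of
tests; 0.0125 for four pairwise comparisons). The divergence matrix is

    D = (MS_H − MS_E) / nf,

with nf the unbalanced one-way effective group size
n₀ = (N − Σn_g²/N)/(a−1), isolated in `effective_family_size` so an
alternative definition can be swapped in. D is symmetrized and
eigen-decomposed; because D is a difference of mean squares its
eigenvalues can be negative — negative eigenvalues are retained in output
but excluded from the "proportion of divergence" denominator so reported
proportions lie in [0, 1]. Eigenvector signs fix the largest-|loading|
element positive. Individual scores are projections of standardized rows
on d_max and d_2.

## Bayesian fitness models (`fitmodels`)

Two binary-response mixed models on the logit scale:

* **Mean model** — outcome ~ habitat + category + habitat×category (fixed)
  + family-in-category + block-in-habitat (random scalar effects), fitted
  per outcome. Categories are the 4 parental ecotypes, 6 unordered F1
  cross types, and F4.
* **Character-state model** — establishment only, one generation at a
  time: habitat fixed effects plus a focal random effect whose 4×4
  unstructured covariance across habitats is the estimand (among
  population for parents, among cross type for F1, among family for F4),
  with nuisance family (parents/F1) and block variances. Residuals are
  independent across habitats because a seed is planted in exactly one
  habitat.

**Sampler.** A fully conjugate auxiliary-mixture Gibbs sampler: the
standard logistic residual density is represented by a zero-mean
8-component normal scale mixture fitted offline by penalized least squares
(sup CDF error < 1e-6, asserted in the tests; mixture variance matches
π²/3 to 4 decimals). Each sweep draws, per seed, a mixture component and a
truncated-normal latent jointly from their exact conditional given the
outcome, after which every update is Gaussian: fixed effects in
habitat×category cell-means coding (diagonal posterior precision; H, C and
interaction contrasts are derived from cell draws), scalar random effects
via bincount-accumulated normal conditionals, and the focal 4-vectors via
batched 4×4 Cholesky solves.

**Priors.** Cell means N(0, 25) on the logit scale. Scalar variances get
half-t(ν = 2, A = 1) priors via the inverse-gamma auxiliary
representation; the focal covariance gets the Huang–Wand
parameter-expanded inverse-Wishart prior (marginal half-t on each standard
deviation, scale A), both conjugate in the augmented model. A prior
sensitivity test doubles A and checks that well-identified variance
posteriors remain within overlapping HPDs.

**Residual scale.** For a Bernoulli response the residual variance is not
identifiable; here the residual is *fixed* as the standard logistic
(variance π²/3, covariances 0), which is exactly the latent scale on which
the generator draws its truth covariances. All reported variances are on
this scale; `marginal_probability` maps latent cell means to data-scale
probabilities by Gauss–Hermite integration over the random-effect
distribution (checked against brute-force Monte-Carlo integration to
0.005).

**Chain settings.** Because every conditional is an exact Gibbs draw, the
sampler needs no tuning and mixes far better per iteration than
random-walk samplers; defaults (4500 iterations, 500 burn-in, thin 2 →
2000 retained draws) and the reduced test settings keep full fits in
seconds to tens of seconds at the design scale of ~21k seeds. Variance
components in these models are nonetheless strongly autocorrelated, so
lag-1 autocorrelation (< 0.05) and Geyer initial-positive-sequence ESS
(≥ 85% of retained draws) are computed per scalar chain, and results
failing either threshold are flagged rather than suppressed; recovery
coverage does not depend on the flags, only interval precision does.
A Gaussian-identity variant of the same sampler (used by the
method-of-moments cross-checks) samples the residual variance with a
vague inverse-gamma prior.

**Trivariate responses.** With one binary observation per seed per outcome
and the residual fixed, an among-outcome residual covariance is not
identifiable; the three outcomes are fitted as separate univariate models,
and `conditional_survival_recode` provides the monotone
(survival-given-previous-stage) coding as the documented alternative.

## Covariance tensor (`tensor`)

The three generation matrices (correlation matrices of the character-state
covariances by default) are vectorized with off-diagonal elements weighted
by √2, so Euclidean inner products of vectors equal Frobenius inner
products of matrices. The covariance of the m = 3 vectors (divisor m−1) is
the S-matrix; its eigenvectors, refolded (off-diagonals ÷√2) into
unit-Frobenius-norm symmetric matrices, are the eigentensors E_k with
eigenvalues α_k (Σα_k = trace S). A generation's coordinate on E_k is
⟨G, E_k⟩; projecting an eigenvector e of E₁ through G gives eᵀGe, the
amount of among-habitat (co)variance G expresses along that axis.

Orientation: an eigentensor with |trace| > 0.1 is oriented trace-positive
(such a tensor describes a same-direction change of all elements — here,
the overall strengthening/weakening of trade-offs — and the trace sign is
the stable way to orient it across Monte Carlo replicates); otherwise the
largest-|element| is made positive.

**Posterior uncertainty** uses a fixed frame: S is the average of per-draw
S matrices, eigentensors are computed once from it, and coordinates,
projections and α are evaluated per aligned posterior draw (draws aligned
by index across the three independently fitted generations). Per-draw
re-decomposition is available behind `per_draw_frame=True`; the fixed
frame keeps eigentensor identity constant so that coordinate HPDs are
interpretable. The m = 2 degenerate case (rank-1 S) is allowed with a log
note.

## Line-cross analysis and the adaptation regression (`adaptation`)

All quantities are computed per posterior draw on the probability scale of
the mean-model predictions: midparent = unweighted mean of the four
ecotype cell means; F1 expectation = midparent (additivity); F4
expectation = midpoint of midparent and the observed F1 mean; heterosis
deviations are observed − expected, with HPDs taken over the per-draw
deviation sequences (never by differencing interval endpoints). Adaptation
strength in a habitat is the native ecotype's predicted fitness minus the
unweighted mean of the three foreign ecotypes'. The regression of a
generation's four habitat fitness variances on the four strengths is an
OLS slope per draw, pairing mean-model and character-state draws by index
(the models are fitted separately; joint draws do not exist, and index
pairing preserves both marginals). Reported: slope posterior summaries,
the fraction of negative slopes, and the highest HPD probability at which
the interval excludes zero (bisection, resolution 0.5%).

## Pipeline (`pipeline`, `cli`)

`run_pipeline` executes simulate → divergence → fitfield (mean model +
three character-state fits) → tensor → adaptation → report. One master
seed spawns a stable stream per stage, so identical configurations give
byte-identical numeric outputs while stages remain individually
rerunnable; `resume=True` skips stages whose outputs exist. Outputs are
CSV/JSON with a Markdown report; every JSON carries the package version,
a config hash and the seed. The `ecotensor` click CLI wraps the stages
(`simulate`, `divergence`, `fitfield`, `tensor`, `validate`, `all`).

## Problem sizes and numerical choices

The default generator scale is the full experimental design (~21k field
seeds, ~780 measured plants); a full pipeline run with 2000 retained draws
per model takes about a minute on one CPU. The test suite uses reduced
designs (the `demo_config` preset, ~8k seeds) and shorter chains
(700–1700 iterations) chosen as the smallest sizes at which the recovery
and pattern checks are statistically decisive; the end-to-end replicate
checks run ten full-scale analyses. Numerical details: eigentensor/
eigenvector sign conventions as above; PSD is enforced on covariance draws
by construction (inverse-Wishart) and verified to an eigenvalue floor of
−1e-10; truncated-normal draws clip quantiles at float limits and bound
latents away from the wrong side of zero; habitats with no outcome
variation flag the fit as degenerate instead of crashing.

## Known limitations

* The parental character-state covariance is estimated from only four
  populations (as in the motivating design); its posterior is strongly
  prior-influenced, which the tensor stage inherits.
* The fixed-frame tensor protocol conditions on the posterior-mean S;
  frame uncertainty itself is not propagated (the per-draw option exists
  for comparison).
* Diagnostics at reduced chain lengths regularly flag variance-component
  chains; the flags are reported, and longer chains/thinning are a config
  change away.
* The adaptation regression has four points per draw; its slope posterior
  is meaningful only as a direction-of-association summary.
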