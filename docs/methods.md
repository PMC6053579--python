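# Methods

`phylodispersal` implements a battery of phylogenetic comparative methods
for the question of sex-biased dispersal in birds: do males and females
differ in how far they move between birth and breeding sites (natal
dispersal) or between successive breeding sites (breeding dispersal), and
does that sex bias track sexual selection, parental sex roles, the adult sex
ratio (ASR), or sex-biased mortality?  This note records the models, the
numerical choices, and the design decisions that were genuinely open.

## Trait derivation

The raw table has one row per species × population.  All derived metrics use
base-10 logarithms, so every "bias" is a log10 ratio and a value of +1 means
the male quantity is ten times the female one.

- **Dispersal bias** (natal and breeding): log10(male km) − log10(female km).
  A population contributes to a dispersal-type mean only when it reports
  *both* sexes for that type: sex comparisons pooled across populations with
  different coverage would confound population and sex effects.  Species
  values are **unweighted** means over qualifying populations (predictor
  variables exist only at the species level, so weighting by population
  effort would be spurious precision).
- **Mating-system bias**: male − female social polygamy score, each on the
  0 (monogamy) … 4 (common polygamy, including lekking males) scale.
- **Relative testes mass**: log10(testis g) − 0.67·log10(male g); 0.67 is
  the cross-species allometric exponent of testis on body mass in birds.
- **SSD**: log10(male g) − log10(female g) (isometric null).
- **Dichromatism**: five body-region scores in −2…2 (positive = male
  brighter); both the mean and the sum are derived.  All five regions must
  be scored — a partial mean would not be comparable across species.
- **Care bias**: mean of up to six component scores in {−1, −0.5, 0, 0.5, 1}
  (positive = more male care), averaged over whichever components are
  scored; species differ in coverage and the component means correlate
  strongly, so the available-component mean is used rather than requiring
  completeness.
- **ASR**: arcsine-square-root transform arcsin(√p) of the proportion of
  males, in radians.  The variance-stabilizing arcsin(√p) form is used; a
  plain arcsin(p) is also monotone on (0, 1), so sign conclusions are
  unaffected by the choice, but slope magnitudes are not comparable between
  the two conventions.
- **Mortality bias**: log10(male annual mortality) − log10(female).

Missingness propagates: a derived value is absent exactly when a required
input is absent, and every downstream model selects its own
pairwise-complete species set, so sample sizes legitimately differ between
analyses.  The per-model species lists are logged for audit.

## PGLS with maximum-likelihood Pagel's λ

The regression model is y = Xβ + ε, ε ~ N(0, σ²·V_λ), with V the
phylogenetic variance–covariance matrix (V_ij = depth of the most recent
common ancestor of species i and j) and V_λ its Pagel transform
(off-diagonal entries multiplied by λ ∈ [0, 1]).  β and σ² have closed-form
ML solutions given λ; the profile likelihood of λ is maximized on [0, 1] by
a 21-point grid followed by bounded Brent refinement, always comparing
against both endpoints — the profile can be multimodal on small trees, and
a pure local optimizer started from one point misses the global mode there.

Estimation is ML (not REML), and standard errors use the residual variance
rescaled by n/(n−k), so t-statistics refer to a t distribution with
df = n − k (k coefficients including the intercept).  No df penalty is
charged for the estimated λ: the t-based test sizes are verified empirically
instead (see Calibration).  At λ = 0 on an ultrametric tree the fit reduces
to OLS exactly; this is asserted to 1e-8 against a closed-form
normal-equations oracle.  Adjusted R² is 1 − (1−R²)(n−1)/(n−k) with R²
computed from GLS-transformed residual and total sums of squares (total
about the GLS intercept-only mean).  λ's upper bound is fixed at 1 for
interpretability even where the matrix would admit slightly larger values.

Degenerate inputs: a constant response makes λ unidentifiable; the fit is
returned with a warning flag rather than an exception.  Covariance matrices
that are numerically semi-definite (trees with near-simultaneous splits, or
zero-length terminal cherries) get an escalating diagonal ridge
(1e-12…1e-8 × mean diagonal) before factorization fails hard.

## Phylogenetic paired t-test

For paired sex-specific values the species difference d_i = log10(male) −
log10(female) is modeled as d = a·1 + ε, ε ~ N(0, σ²·V_λ), with λ and σ²
estimated by ML jointly with the phylogenetic (GLS) mean
â = (1ᵀV_λ⁻¹1)⁻¹1ᵀV_λ⁻¹d.  The standard error is
√(σ̂²_ML · n/(n−1) · (1ᵀV_λ⁻¹1)⁻¹) and the reference distribution is t with
df = n − 1 — the mean is the only mean-structure parameter.  (Charging an
extra df for the estimated λ is a defensible alternative; the empirical
size at n = 50 is within ±0.02 of nominal under the n − 1 convention, which
settled the choice.)  On a star phylogeny the statistic equals the
classical paired t exactly.  Working on log10 distances makes "mean
difference ≠ 0" equivalent to "median male/female distance ratio ≠ 1".
Identical paired vectors return t = 0, p = 1 exactly.

## D statistic for binary traits

The raw statistic sums |parent − child| nodal-value changes over all edges,
with internal nodal values estimated by unweighted averaging of daughter
values (tips carry 0/1).  Branch lengths deliberately do not enter the
nodal estimation — this reproduces the original statistic rather than an
ancestral-state-reconstruction variant — and enter only through the
Brownian simulations.  The observed sum is scaled against two null
ensembles on the same tree:

- **permutation null** (D = 1): observed states shuffled among tips;
- **Brownian threshold null** (D = 0): a continuous Brownian character
  simulated on the tree and dichotomized by giving state 1 to the k tips
  with the largest values, k fixed at the observed count — the empirical
  per-replicate quantile guarantees the observed prevalence exactly, with
  ties broken by a stable rank under the seeded generator.

d = (obs − mean_Brownian)/(mean_random − mean_Brownian); values outside
[0, 1] are meaningful (overdispersion above 1, extreme clumping below 0).
P1 = Pr(permutation sum ≤ observed), so small P1 rejects phylogenetic
randomness; P0 = Pr(Brownian sum ≥ observed).  Defaults are 1000
permutations and 1000 simulations.  Because nodal averaging is linear in
the tip vector, the whole statistic is precomputed once per tree as a pair
of edge-weight matrices, making the null ensembles a single matrix product
each — the 100-tree calibration study runs in seconds.

A note on the maximal case: on a balanced four-tip tree with alternating
states, daughter averaging puts 0.5 at every internal node, so the
edge-change sum is 2.0 (four tip edges × 0.5), which is the ceiling for
this estimator on that tree.

## Tree ensembles

Phylogenies are uncertain, so each model is refit on every tree of an
ensemble and combined: mean slope across trees, and total
SE = √(V1² + V2²) with V1² the mean squared per-tree SE and V2² the squared
*sample* (n−1) standard deviation of the slopes across trees.  The SD —
not SD/√N — convention is deliberate: V2² quantifies between-tree
(phylogenetic) dispersion, which should not vanish as more trees are drawn
from the same posterior; the SD/√N alternative is available behind a
switch.  p-values are reported as mean ± standard error of the mean across
trees, with no meta-analytic transformation.  Per-tree failures are
recorded and excluded; an all-tree failure raises.

## Pipeline

The full battery runs both paired tests, the 2 × 8 response × predictor
PGLS grid minus the natal-bias × mortality-bias cell (left untested:
mortality samples exclude pre-breeding dispersers), plus the
natal-vs-breeding-bias model, each as a tree ensemble on its
pairwise-complete species set, with models under 10 species skipped with a
recorded reason (10 being the conventional floor for a two-parameter PGLS;
configurable).  D tests run on the sign of each bias (1 = male-biased); by
default on the first tree of the ensemble, configurable to more.
Sensitivity variants rerun the grid excluding hunted species, dropping
named species (outlier handling is by explicit name only — no automated
outlier rule), or adding the ASR estimation method (census vs capture) as a
dummy-coded two-level covariate, and report baseline and variant estimates
side by side.

## Synthetic data

The generator emulates the statistical structure the analyses assume, not
bird taxonomy.  Trees are Yule (pure-birth) — the simplest ultrametric
generator; topological fidelity to real avian phylogenies is irrelevant for
validating the estimators.  Continuous characters are exact multivariate
normal draws with covariance σ²·V_λ via Cholesky factorization, on a tree
rescaled to unit mean depth so variance parameters are comparable across
tree draws.  Discrete scores (polygamy, dichromatism, care) are produced by
thresholding latent Brownian characters into the legal categories, which
preserves phylogenetic signal in the discrete predictors.  Defaults mirror
the shape of a real comparative study of this kind: 86 species, 100-tree
ensembles, female-biased dispersal (mean log10 ratio −0.15 with residual
variance 0.16, chosen so a ~60-species paired test is significant but not
overwhelming), 30% per-variable-group missingness (producing the
characteristic spread of per-analysis sample sizes), 1–3 populations per
species with 0.05 log10-scale jitter, and 15% hunted species.  Missingness
is completely at random, matching the pairwise-deletion analysis; real
literature data are *not* missing at random, so the pipeline's behavior
under informative missingness is untested.  An optional generative link
from arcsine-ASR to breeding bias supports pipeline-level
slope-sign-recovery checks.

## Calibration studies and problem sizes

The validation suite and the reproduction script run simulation studies at
these sizes, chosen to give Monte-Carlo error comfortably inside each
check's tolerance: D calibration on 100 trees of 50 tips with 1000
permutations and simulations each (mean scaled D within ±0.1 of its
anchors); λ recovery with 200 replicates at n = 200 tips per generative
λ ∈ {0, 0.5, 1} (median within 0.1); slope recovery with 500 replicates at
n = 100 (|bias| < 5%); empirical test sizes with 1000 replicates at n = 50
(within 0.05 ± 0.02).  Tree pools of 10 trees are cycled across replicates
within a study; each replicate draws fresh traits.

## Known limitations

- Simulated missingness is MCAR; passing tests say nothing about biased
  literature coverage.
- The D statistic's Brownian null assumes an ultrametric tree; non-
  ultrametric input warns but proceeds.
- No measurement-error model: within-species sampling variance of the
  distance means is ignored, as in standard PGLS.
- λ is bounded at 1; traits with accelerating divergence are truncated to
  the Brownian expectation.
- p-value aggregation across trees is descriptive (mean ± SE), not a
  combined test.
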