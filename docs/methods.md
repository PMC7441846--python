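# Methods

This note documents the statistical procedures, the synthetic data model,
the numerical conventions, and the design choices made where the underlying
methodology left the design open.

## The analysis chain

The package studies how trustworthy geographically aggregated questionnaire
scores are. The chain is: score individuals from sparse item responses →
aggregate to unit (state) means → ask (i) how much variance unit membership
explains and how reliable the unit means are, (ii) whether independent
samples' unit means agree, (iii) whether different inventories rank units
the same way, and (iv) whether unit-level correlations with external
sociodemographic variables replicate across samples.

### Scoring under planned missingness

Individual trait scores are the simple mean of the observed items for that
trait within one inventory. Reverse-keyed items are reflected as
`likert_min + likert_max − x` before averaging. `min_items` (default 1)
sets the floor on observed items per trait; there is no imputation and no
IRT/factor scoring — with items missing completely at random by design, the
observed-item mean is an unbiased (if noisy) estimate of the full-scale
mean, and the downstream analyses only consume means and variances.

Unit scores are unweighted means over the participants residing in the unit
(each participant counts once; no post-stratification). The unit universe
is configurable per stage — all 51 units (50 states + DC), the contiguous
48 + DC, or the contiguous 48 — because different data sources cover
different subsets.

### ICC1, ICC2, and k

ICC1 is estimated by one-way random-effects ANOVA on (generally unbalanced)
groups: `ICC1 = (MS_B − MS_W)/(MS_B + (k − 1) MS_W)`. ICC2 is the
Spearman–Brown step-up `k·ICC1/(1 + (k − 1)·ICC1)`, the reliability of a
mean of k observations; equivalently, the expected correlation between the
unit means of two equally sized random samples from the same population.

Two conventions for k are provided: the arithmetic mean group size
(default, matching how "average participants per state" is reported) and
the unbalanced-design effective size `k0 = (N − Σn_j²/N)/(J − 1)`. With the
rank-size population weights used here the two differ by ~10–20%; at the
ICC1 magnitudes involved the resulting ICC2 difference is small but not
zero, which is why both are exposed.

Cross-trait summaries average per-trait ICC1s and per-trait ICC2s
arithmetically. Because the Spearman–Brown relation is nonlinear, the mean
ICC2 is *not* the step-up of the mean ICC1; the two summaries are
deliberately reported side by side and must not be converted into each
other.

Negative ICC1 estimates (MS_B < MS_W) are reported unclipped. The
Spearman–Brown denominator `1 + (k − 1)·ICC1` can then be nonpositive for
large k; `spearman_brown` raises on that degenerate input, and the table
routines record the ICC2 as missing with a warning.

### The permutation null

Because the ICC1 values of interest are tiny (~0.003), the package provides
a permutation null: participants are randomly reassigned to units without
replacement, keeping every unit's participant count fixed, and ICC1/ICC2
are recomputed per iteration. Since the total sum of squares is
permutation-invariant, only group sums are recomputed per iteration, which
makes thousands of iterations cheap. Under the null the mean ICC1 vanishes
(zero to four decimals at 500+ iterations) and the mean ICC2 is slightly
*negative* — the step-up of an ICC1 distribution centered at zero is
concave, so E[ICC2] ≈ −k(k−1)·Var(ICC1) < 0. A fixed-quota assignment mode
in the generator supports exactly this design (constant per-unit counts).

### Convergence and Fisher pooling

Same-trait correlations between two samples' state score tables are
weighted Pearson correlations with frequency-normalized weights (weights
enter the means, variances and covariance; the estimator is scale-invariant
in the weights). Census population counts are the weights, so thinly
sampled units contribute less. All pooling of correlations goes through
Fisher's z: `tanh(mean(atanh(r)))`. Inputs of exactly ±1 (which occur in
self-pair checks) are clipped to ±(1 − 1e-12) with a warning.

Sample pairs are classified by three design facets: same/different
inventory, same/different project, and time period Same / Adjacent /
Non-adjacent. The time rule: periods sharing more than a boundary year are
Same; touching at a single year or separated by less than `gap_years`
(default 5) are Adjacent; gaps of 5+ years are Non-adjacent. Real
collection "eras" do not always follow period geometry, so
`pairwise_convergence` accepts explicit per-pair design overrides.

### Split-half cross-inventory convergence

When several inventories are administered to one sample from overlapping
item pools, individual-level cross-inventory correlations are inflated by
shared items. The split-half bootstrap avoids this at the unit level: each
iteration splits participants uniformly at random into two halves, scores
each inventory in each half, aggregates, and correlates inventory A's state
scores in half 1 with inventory B's in half 2. Both orderings
(A₁×B₂ and B₁×A₂) are recorded and averaged. The diagonal — an inventory
correlated with itself across halves — is the split-half reliability of its
aggregated scores; off-diagonal cells divided by the square root of the
product of the two reliabilities estimate the latent same-trait
correlation, reported unclipped (values slightly above 1 are sampling
noise, not errors). Cross-iteration pooling uses Fisher z by default; raw
averaging is available (`pooling="raw"`) since either convention is
defensible and they differ only in the third decimal at these magnitudes.
A `degenerate=True` hook places the whole sample in both halves, reducing
every cell to the full-sample cross-inventory correlation — used to anchor
the machinery in tests.

### Representativeness

Participant counts per unit are correlated (unweighted Pearson) with census
populations; within-unit composition percentages are correlated per
category with census margins (margins accepted as counts or proportions —
rows are renormalized). Educational attainment uses the age-eligible
convention: percent of participants over 17 with at least a high-school
credential, and over 24 with at least a bachelor's degree. Age bands
default to 18–24, 25–44, 45–64, 65+. The sample summary reports the median
age with its median absolute deviation both raw and scaled by 1.4826 (the
normal-consistency constant), since reporting conventions differ.

### Sociodemographic replication

Correlations between a sample's state trait scores and unit-level
sociodemographic variables are weighted and partialled for the sample's
other traits. The partial correlation is computed from the weighted
correlation matrix of (x, y, controls) in Schur-complement form: the
controls' correlation block is inverted explicitly, so collinear controls
produce an error naming the offending columns. If x or y is an *exact*
linear function of the controls the partial correlation is a 0/0 limit; it
is returned as 0 with a warning (a zero-variance residual is orthogonal to
everything by convention). An independent residualization route (correlate
the weighted-least-squares residuals) is kept as a test oracle.

Replicability is the correlation of correlations: every (old sample, new
sample, variable) combination contributes one pair of correlation values,
and the Pearson correlation over the pairs — per trait — is the replication
correlation. The per-trait range (max − min over the pooled old+new cells)
diagnoses restriction of range. No multiple-testing correction is applied
anywhere: the analysis reasons through patterns and means of correlations,
and `critical_r(n, alpha)` (via `r = t/sqrt(t² + n − 2)`) is provided as a
descriptive yardstick only. Units with missing values are handled
pairwise-complete with a logged count.

## The synthetic data model

The generator emulates the structure of large online assessments
aggregated to states, with every latent quantity recorded as ground truth:

* **Units.** 51 units labelled with postal codes; population weights follow
  a rank-size (Zipf, exponent 1) law, giving a largest/smallest ratio of 51
  (real state populations span a ratio of ~66). Participants are assigned
  multinomially by weight, or by fixed quota for permutation-null designs.
* **Traits.** Unit latent means are `m_t + N(0, between_unit_sd)`;
  participant traits add `N(0, within_unit_sd)`. The implied latent ICC1,
  `b²/(b² + w²)`, is recorded as ground truth. Defaults: within-unit SD 1.1
  (matching the ~0.9–1.2 individual score SDs typical of 1–6 Big Five
  scales) and between-unit SD 0.06, i.e. latent ICC1 ≈ 0.003 — the regime
  of interest. `between_sd_for_icc` calibrates the between-unit SD for an
  exact target.
* **Items.** Response = `clip(round(m_t + loading·(τ − m_t) + N(0, 0.8)),
  1, 6)`, with reverse-keyed items generated reflected. The linear
  latent-plus-Gaussian model is deliberately minimal: only means and
  variances matter downstream. Inventories sample their items independently
  per participant at inventory-specific rates, and may share items with an
  earlier inventory (`overlap_with`/`overlap_fraction`), mirroring
  inventories drawn from a common public-domain pool.
* **Census.** Unit populations are apportioned from the weights
  (largest-remainder). Demographic margins (ethnicity, age band, education)
  are per-unit Dirichlet draws around national base proportions with
  concentration 15, chosen so the cross-unit spread of category shares
  matches the wide variation of real state composition (minority shares
  ranging from under 1% to over a third). Participant demographics are
  drawn from their unit's margins.
* **Sociodemographics.** Each variable is a loading-weighted combination of
  the standardized unit trait means plus Gaussian noise. With
  `noise_sd=None` the noise is auto-calibrated to `sqrt(1 − Σr²)` so the
  configured correlations hold exactly in expectation; explicit noise
  rescales the loadings accordingly. Realized correlations are recorded.
  The default 13-variable set loads moderately on Conscientiousness,
  Neuroticism and Openness and weakly on Extraversion and Agreeableness,
  emulating the empirical pattern that only some traits have consistent
  state-level correlates.
* **Reproducibility.** One integer seed; independent sub-streams (item
  bank, unit assignment, latent traits, responses, census margins,
  sociodemographics, demographics) derived by `SeedSequence.spawn` in a
  fixed order, so a fixed seed fixes every artifact bit-for-bit.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: response styles (acquiescence, careless
responding), non-random missingness, facet structure within traits,
measurement non-invariance across inventories, real demographic joint
distributions, or non-representative recruitment (participants are drawn
proportional to the census by default). Tests against this generator
validate the *estimators* under the intended model, not the substantive
claims of any geographic-psychology analysis.

### A note on what "recovery" means for ICC1

The generator's ground-truth ICC1 lives on the latent trait scale. The
ANOVA estimate operates on observed scores, which carry item noise
(variance 0.64 divided by the number of observed items per trait) plus
rounding/clipping variance, so the estimate is attenuated by roughly 10% at
the default 30% sampling of a 20-item-per-trait inventory — e.g. ~0.0027
observed for a latent 0.0030. Recovery tests therefore compare the mean
estimate across the five traits at n = 1e5, where Monte-Carlo noise per
trait (SD ≈ 0.0007) still dominates the attenuation. Recovery runs use
mid-scale trait means (3.5 on 1–6) so Likert clipping is symmetric and does
not bias unit means; the study-like default keeps realistic off-center
means, under which clipping compresses the upper tail.

## Problem sizes in the shipped tests and scripts

The test suite and the acceptance script scale the simulations to what the
estimators need rather than to the original studies: ICC recovery at
n = 1e5 (51 units, k ≈ 1960), permutation nulls at 51 units × 500
participants × 500 iterations per trait, split-half checks at n = 2·10⁴
with 30–100 iterations, and Monte-Carlo calibration checks over 200–1000
seeds of unit-level draws. These sizes keep the full suite under a minute
of simulation time while leaving every assertion's tolerance dominated by
the statistic's own sampling error.

## Known limitations

* ICC variants beyond one-way ICC(1)/ICC(1,k) — two-way designs, REML mixed
  models — are out of scope.
* The cross-sample convergence panel is not adjusted for ICC2 attenuation
  (the split-half stage handles disattenuation where it is well-defined).
* Weighted partial correlations assume the weighted correlation matrix is
  well-conditioned; near-singular control sets (condition number > 1e12)
  are rejected rather than regularized.
* The time-period design classification is geometric; era-based
  classifications of real studies may require explicit overrides.
* Scoring assumes items are missing by design (completely at random);
  systematically missing items would bias observed-item means in ways the
  package does not model or detect.
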