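# Methods

## Model and estimand

A two-arm randomized trial with binary adverse outcome is modeled in
the potential-outcomes framework: participant *i* has `Y1_i, Y0_i ∈
{0,1}` and individual treatment effect `δ_i = Y1_i − Y0_i ∈ {−1, 0, 1}`
(benefit, none, harm).  The estimand is the subgroup-level average
treatment effect (ATE): the mean of `δ` over a covariate-defined
subgroup, estimated in the trial by the within-subgroup risk difference
between arms.  The package's purpose is to *discover* subgroups whose
ATEs differ, while keeping treated and control participants inside each
discovered subgroup comparable on the chosen prognostic covariates.

Assumptions: complete data (missing covariates are an input error, not
imputed), 1:1 randomization, binary outcome, and that the covariates
worth balancing are measured.  Unmeasured confounding within subgroups
is out of reach by construction and acknowledged as a limitation.

## The matched pipeline

**Distance.**  Continuous covariates enter as-is, binary as 0/1,
categorical as L−1 indicators (lexicographic reference level).  Every
encoded column — indicators included — is replaced by its within-sample
ranks (average ranks on ties), and distances are Mahalanobis with
respect to the sample covariance S of the ranked columns (Rosenbaum's
rank-based Mahalanobis distance).  Ranking the indicator columns is an
affine relabeling, so it affects nothing beyond the covariance
weighting.  S is inverted by Moore–Penrose pseudo-inverse (`pinvh`):
indicator blocks can be collinear in small trials and the metric should
degrade gracefully rather than fail.  Zero-variance columns are dropped
with a warning.

**Matching.**  Optimal bipartite assignment (Jonker–Volgenant via
`scipy.optimize.linear_sum_assignment`) produces G = min(C, T) disjoint
pairs minimizing total distance.  The solver is deterministic for a
fixed matrix; with continuous covariates exactly tied optima have
probability zero.  A greedy nearest-neighbor matcher is available
(`matcher="greedy"`) for sensitivity analysis only.

**Exact filter.**  Pairs disagreeing on any listed categorical variable
are discarded (binary prognostic variables are treated as categorical
for this purpose; the list is user-configurable and defaults to every
non-continuous prognostic covariate).  The first mismatching variable
is recorded as the discard reason.  Averaging an unequal categorical
value is refused rather than interpolated, so disabling the filter
cannot silently produce meaningless rows.

**Averaged data.**  Each retained pair g contributes one row:
`δ_g = Y_g^t − Y_g^c` and the pair-mean of continuous covariates (the
filtered categorical values are shared by construction).

## The conditional inference tree

At each node, every candidate covariate is tested for independence
against the response with the standardized linear permutation statistic
`T = Σ g(x_i) y_i` (identity influence for numeric x, one indicator per
level for categorical x), standardized by its exact conditional mean
and covariance under permutation of y.  The quadratic form of the
standardized statistic is referred to a chi-square distribution with
degrees of freedom equal to the rank of the conditional covariance.
For node sizes ≤ 10 the permutation distribution is enumerated exactly
(over distinct rearrangements of y, capped at 2·10⁵ arrangements); the
asymptotic reference is unreliable there and δ-valued responses make
exact enumeration cheap.

The node splits only when the smallest Bonferroni-adjusted p-value
(times the number of candidate variables, capped at 1) is ≤ α.  The
selected variable's cutpoint is then found by exhaustive search:
numeric variables over every midpoint between consecutive distinct
values, categorical variables over every binary level partition (≤ 10
levels; the bundled designs have ≤ 4), maximizing the standardized
two-sample mean-difference statistic subject to both children holding
at least `min_leaf` rows.  Ties keep the smallest threshold /
lexicographically first level set, so fits are bit-reproducible.
Growth is iterative (explicit stack), terminal nodes are numbered in
depth-first preorder, and routing uses the inclusive-left convention
(`x ≤ c` goes left, boundary included).

δ_g is treated as a *numeric* response (its node mean is exactly the
quantity the subgroup report estimates), which makes the variable test
a mean-shift test.  The per-node Pr[δ = −1/0/+1] estimates reported for
each subgroup are the empirical δ_g frequencies of the node's pairs —
the only distributional information the tree retains.

### Parameters

| parameter   | default      | meaning / rationale                                   |
|-------------|--------------|-------------------------------------------------------|
| `alpha`     | 0.05         | adjusted-p threshold to split; the standard level of the conditional-inference framework |
| `min_split` | 20           | smallest node considered for splitting (framework default) |
| `min_leaf`  | 7            | smallest admissible child (framework default)          |
| `adjust`    | bonferroni   | multiplicity adjustment across candidate variables     |

The α = 0.05 stopping rule means that, by design, a null node splits
with probability ≈ α: across many replicates a minority of fits will
carry one extra, spurious subgroup.  The test suite verifies both sides
of this calibration (null any-split rate ≤ α + 0.03 over 200
replicates; root stays terminal in ≥ 90/100 pure-noise fits).  Users
wanting fewer, larger subgroups should lower `alpha` — trees at smaller
α are exact prunings of trees at larger α (verified property).

## Effect estimation and diagnostics

Subgroup risk differences get a normal-approximation CI.  The default
carries the Yates continuity correction — half-width plus
`(1/n_t + 1/n_c)/2`, as in R's `prop.test` — which is the variant that
reproduces published trial intervals of this kind at printed precision;
`cc=False` gives the plain Wald interval.

Balance is measured by absolute standardized differences:
`|m_t − m_c| / sqrt((s_t² + s_c²)/2)` for continuous covariates (sample
variances, n−1; population-variance versions are indistinguishable at
the 2-decimal reporting precision) and
`|p_t − p_c| / sqrt((p_t(1−p_t) + p_c(1−p_c))/2)` for proportions, with
multi-level categoricals reported per level and summarized by the
maximum.  A subgroup is "balanced" when all ASDs < 0.2 (configurable
cutoff).  Degenerate cases: identical constant groups give ASD 0,
unequal constants give +inf.

Bias, available when simulated truth is attached, is the node's
estimated risk difference minus the mean true δ of its members.  The
two-proportion design formula (`required_sample_size`) is the pooled
normal approximation without continuity correction, ceiling-rounded.

## Comparators

The logistic comparator fits outcome ~ main effects + treatment + all
treatment×covariate interactions and removes one term per step —
whichever removal most decreases AIC — under a hierarchy constraint (a
main effect is only removable after its interaction, the treatment
term after all interactions), then computes per-participant effects
`p1 − p0` by toggling the treatment column.  The RF comparator is a
500-tree majority-vote classification forest (√p features per split)
applied with treatment forced to 1 and to 0.  A gradient/causal forest
slot exists as a registration-based adapter; with no backend registered
it reports "skipped" explicitly.  Each comparator's effects are
partitioned into subgroups by the same conditional inference tree
(identical defaults, for comparability), and reported with the same
risk-difference/balance/bias schema as the matched pipeline — which is
what exposes their covariate imbalance.

## The simulators

Five bundled designs, two settings.  Oncology (n = 200): age ~ N(65,5),
stage-4 ~ B(0.98), site ~ Multinom(0.5, 0.17, 0.33), previous treatment
~ Multinom(0.5, 0.2, 0.2, 0.1), ECOG ~ B(0.55), disease-free interval
~ B(0.35); δ ~ Multinom(0.5, 0.2, 0.3) for all (1A) or split at age 65
into (0.6, 0.2, 0.2) / (0.4, 0.2, 0.4) (1B); δ = 0 implies Y1 = Y0 = 1.
CVD (n = 6000): ten covariates (age, black race, SBP, DBP, creatinine,
eGFR ~ N(72, 20), statin, aspirin ~ B(0.51), Framingham score, smoking
status); δ ~ Multinom(0.068, 0.88, 0.052) for all (2A), or per
aspirin × eGFR-vs-72 cell with subgroup ATEs (0, +0.096, −0.112,
−0.048) (2B) or (+0.048, +0.112, −0.112, −0.048) (2C); δ = 0 implies
Y1 = Y0 = 0 (forced by the designed arm-level event rates 0.052/0.068).
The eGFR boundary value 72 belongs to the "≤" cell; the age-65 boundary
in 1B likewise (a measure-zero choice for continuous draws).

Randomization is complete (exactly n/2 treated, a seeded permutation).
Draw order is fixed — covariate columns in schema order, then δ via a
single uniform per participant inverted through the cell's multinomial
CDF, then the arm permutation — from numpy's PCG64 `default_rng`, so a
seed pins the dataset byte-for-byte.  Continuous covariates are not
truncated; negative creatinine is possible in extreme tails and
harmless for the methods exercised.

What the simulators do *not* emulate: covariate correlation (all
covariates are drawn independently), measurement error, missingness,
non-compliance, censoring, or continuous/survival outcomes.  Passing
tests therefore demonstrate the method's behavior under clean,
independent covariates with exactly cell-constant effect multinomials —
not performance on messy real trial data.

## Problem sizes used in the checks

The multi-seed checks use 20 replicates per design (seeds 0–19 in the
test suite; seeds derived from `--seed` in `scripts/acceptance.py`), the
two n = 6000 designs at full size, permutation-oracle comparisons at
n ≤ 8, Monte-Carlo p-value cross-checks at 50,000 draws, and null
calibration at 200 replicates — sizes at which every quantity checked
is stable to well within its asserted tolerance.

## Known limitations

* The exact-categorical filter discards ~5–10 % of pairs in the large
  designs; in pathological inputs (arms disjoint on a categorical) no
  pairs survive and fitting fails with an explicit error.
* Matching quality degrades as K grows relative to n; with n = 200 and
  K = 6 the pipeline rarely detects the designed oncology heterogeneity
  (an expected small-sample insensitivity, visible in the 1B design).
* An α-level stopping rule leaves an irreducible α-rate of spurious
  extra subgroups across replicates; such nodes are typically small and
  may individually exceed the 0.2 balance cutoff even though the
  dominant four-node fits are well balanced.
* Subgroup CIs carry no multiplicity adjustment across subgroups.
* Pairs whose members straddle a true subgroup boundary (e.g. eGFR just
  above vs. just below 72) dilute the averaged-data signal and blur the
  estimated cutpoint around the true changepoint.
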