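# Methods

This note documents the models and procedures implemented in `cardioml`,
the parameter defaults and why they were chosen, what the synthetic cohorts
do and do not emulate, and the numerical choices made where the design was
genuinely open.

## Data model and preprocessing

A cohort is a table of per-patient features with a binary disease label
(`cardio`, 1 = disease present).  The default schema carries 12 features:
age (years), gender, height (cm), weight (kg), systolic and diastolic blood
pressure (mmHg), cholesterol and glucose grades (ordinal 1–3), smoking,
alcohol and physical-activity flags, and body-mass index.  Schemas are
user-suppliable; every stage operates on the generic
(matrix, label vector, schema) container.

* **Missing values** are handled at load time only: rows with missing cells
  are dropped (default) or rejected; no imputation is attempted.
* **Standardization** uses the population (divide-by-*n*) standard deviation,
  so the documented test values are exact.  Constant columns map to zeros; a
  column whose computed standard deviation is below `1e-12·(1+|mean|)` is
  treated as constant, because floating-point summation can leave a
  `~1e-15` residual that would otherwise amplify rounding noise to unit
  variance.
* **Leakage policy**: the scaler is fit on the training partition and applied
  to the test partition; SMOTE balances the training partition only.
  Outlier screening runs before the split — it is unsupervised, uses its own
  internal standardization for distances, and never sees a label.
* **Splits** are stratified: per class, `round(count·test_fraction)` records
  are drawn by a seeded permutation; realized counts are within one record of
  the target per class.

## Outlier screening by k-means

Centers are initialized at K distinct randomly chosen records; assignment is
by minimum Euclidean distance (lowest cluster index wins exact ties);
centers are recomputed as cluster means; iteration stops when the
within-cluster sum-of-squares criterion J changes by less than ξ (default
`1e-6`, `max_iter` 300).  Empty clusters are re-seeded from the record
farthest from its center, which leaves J unchanged (the re-seeded center has
no members), so the recorded J history is monotone non-increasing.  Five
random restarts are used by default and the lowest-J run kept; on all small
instances in the test suite this attains the exhaustively enumerated optimum.

Screening removes, in one pass, every cluster whose size is below
`min_cluster_fraction · n` (default 0.10, K default 3) and refuses to delete
half the data.  The silhouette index — mean of `(b−a)/max(a,b)`, singletons
contributing 0 — is computed before removal and again on a refit (same K) of
the surviving records.

Two behaviours of this rule are worth knowing.  First, on a cohort whose
bulk is a single cloud, the deleted far cluster's members have silhouette
≈ 1, so removing them typically *lowers* the mean silhouette; the silhouette
gain the procedure is meant to deliver appears when the bulk has genuine
cluster structure and the outlier cluster usurps one of the K centers (the
planted-cluster fixture in the tests is built that way).  Second, in higher
dimensions the below-fraction rule occasionally co-removes a small extreme
shell of the bulk in addition to the planted cluster; this trims extreme
records and is accepted behaviour of the rule as specified.

## SMOTE

Each synthetic minority record is `x_i + u·(x_nn − x_i)` with `x_i` drawn
uniformly from the minority class, `x_nn` uniformly from its k Euclidean
nearest minority neighbours (k default 5, the canonical choice), and
`u ~ U(0,1)`.  The parity target appends exactly `majority − minority`
records.  Binary/ordinal columns are interpolated and left continuous by
default, faithful to plain SMOTE; an optional rounding post-step exists and
is off by default.  Geometry is assertable: every synthetic point lies on a
minority k-NN segment to within 1e-9.

## Recursive feature elimination

The base ranker (default: L2 logistic regression on internally standardized
features, `|coefficient|` as importance; a decision-tree alternative uses
impurity importance) is refit after each elimination and the least important
feature dropped (ties: the higher column index goes first).  Elimination
continues to the last feature, so the ranking is a total order 1..d and the
selected set of size `n_select` (default 5) is exactly ranks ≤ `n_select`
— which makes selections nested across `n_select` values.

## Attention-GRU classifier

Tabular records have no time axis; the convention here is one feature per
time step with scalar input.  A one-parameter scorer gives relevance
`e_t = tanh(w_a·x_t + b_a)`; softmax turns scores into weights `α` summing
to 1; the GRU consumes the elementwise weighted sequence `α_t·x_t` (the
scalar summary `μ = Σ α_t x_t` is also exposed).  Two GRU layers (default 8
units each) run stepwise, layer 2 reading layer 1's hidden state; the final
hidden state passes through a fully connected layer and a sigmoid.  The cell
blends candidate and previous state as `h_t = (1−v_t)·λ_t + v_t·h_{t−1}` —
the update gate multiplies the *previous* state, the transpose of some
textbook conventions, and is used exactly in that form throughout.

The network is trained derivative-free: all parameters flatten to a single
vector (documented stable layout; 683 parameters at d=5, hidden (8,8)) and
the optimizer searches the box `[−2, 2]` per weight.

**Objectives.** The fitness operation offers mean absolute percentage error
`(1/N) Σ |E_i − e_i| / max(|e_i|, ε)` (ε default 1e-7), cross-entropy, and
0/1 error rate.  MAPE is the interface default, but the *pipeline* trains
with cross-entropy: against a 0-label the ε-guarded MAPE multiplies the
error by 1e7, so on balanced data the objective is dominated by the healthy
class and its minimizer is the constant-0 predictor — a degenerate
classifier.  Cross-entropy preserves the intent (penalize probability error,
lower is better) without the degeneracy.

## Swarm optimizer

A population (default 30) of parameter vectors is initialized uniformly in
the box.  Per iteration, member velocities update as
`υ ← η[υ + m1(p_i − x_i)·x1 + m2(p_β − x_i)·x2]` where `p_i` is the member's
personal best, `p_β` the personal best of a uniformly drawn member (the
social attractor), `x1, x2` per-dimension U(0,1) draws, and
`η = 2/|2 − τ − √(τ² − 4τ)|` with τ = 4.125 (τ > 4 enforced so the root is
real; η ≈ 0.70346).  Positions move by `x ← x + f·υ` with the constant step
scale `f = f_min + (f_max − f_min)/(f_max + f_min)` (defaults 0.07, 0.75 ⇒
f ≈ 0.899) and clamp to the box.  The learning factors m1 = m2 decay
linearly from 2.5 to 0.5 over the run.

After the move, each member may undergo uniform crossover with the global
best (each coordinate swapped with probability ½) and additive Gaussian
mutation (scale 0.1 of the bound range), each triggered with a
fitness-adaptive probability: members at or above average quality get
`L_min + (L_max − L_min)/(1 + exp((K′ − K_avg)/(K_max − K_avg)))` (quality K
is the negated loss), members below average get `L_max` (defaults 0.1, 0.9).
Candidates are accepted only on improvement, so the best-so-far history is
monotone non-increasing by construction and is emitted as the convergence
curve.

Design choices made where the recipe was open: the personal best serves as
the subgroup best (subgroup = singleton); β is a uniform member index; bound
handling is clamping; the optimizer minimizes, with "maximum fitness"
language mapped to the best (lowest-loss) member.

## Synthetic cohorts and what they show

Continuous features are Gaussian (age N(54,7), height N(165,8), weight
N(74,12), systolic BP N(128,18), diastolic BP N(82,10), BMI N(27,4)), flags
Bernoulli (gender 0.35, smoke 0.09, alcohol 0.05, active 0.80), grades
ordinal on {1,2,3}; values resemble published screening-cohort summaries and
are fixtures, not claims.  The label is Bernoulli of a logistic in the
standardized informative features — systolic BP, cholesterol, age, smoking,
weight, with coefficients (2.2, 1.8, 1.6, 1.4, 1.2) and intercept −3.5 —
then a surplus pool is subsampled to hit the 80/20 class split exactly
(within one record).  The coefficient magnitudes put the cohort in the
strongly separable regime (Bayes-reference AUC ≈ 0.95) that screening
studies reporting near-unity AUCs occupy; the Bayes-reference AUC computed
from the true probabilities is the ceiling any classifier can approach on a
draw.  Outliers are a compact cluster displaced by 10 per-column standard
deviations along every continuous dimension (within-cluster spread 0.3 sd),
so the smallest-cluster rule has a correct answer by construction.

What passing tests on these cohorts do **not** show: performance on real
screening data (no measurement error model, no missing-data mechanism, no
correlated features beyond the planted signal, no label noise beyond the
logistic draw), and nothing about cohorts whose minority structure SMOTE
handles poorly (disjuncts, categorical-heavy schemas).

## Problem sizes and defaults used in tests

The reference protocol is n = 2000 records, 5% planted outliers, 80/20 split
imbalance, test fraction 0.2, SMOTE to parity, RFE to 5 features, hidden
units (8,8), population 30, 60 optimizer iterations — a size at which the
full pipeline runs in tens of seconds on one CPU and all end-to-end
properties (majority-rate exceedance, SMOTE recall gain over 10 seeds,
feature and outlier recovery) are measurable with comfortable margins.
Optimizer benchmarks use the standard sphere and Rastrigin functions at
dimension 5.

## Known limitations

* Swarm training in a ~700-dimensional weight space is noisy; the trained
  network typically trails the logistic-regression baseline on these
  linearly generated cohorts (the planted signal *is* linear, so LR is
  near-Bayes here).  The package's claims are the qualitative ones the tests
  assert, not parity with gradient training.
* MAPE as printed is retained for interface fidelity but is unsuitable as a
  training objective on 0/1 labels (see above).
* The attention scorer has a single weight/bias pair; it modulates feature
  magnitudes but cannot learn feature-pair interactions by itself.
* Outlier screening assumes contamination forms small, displaced clusters;
  diffuse contamination (i.i.d. extremes) will not form a small cluster and
  will largely survive screening.
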