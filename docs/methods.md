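# Methods

## Problem and model

A functional brain network (FBN) represents each brain region of interest
(ROI) as a node and the statistical dependence between two regions' activity
time courses as an edge weight. Given a per-subject data matrix
X ∈ R^(t×n) (t time points, n ROIs; the package's study-scale defaults are
t=170, n=116, matching a short resting-state scan parcellated with an
AAL-style atlas), each column is first *standardized*: centered and scaled
to unit Euclidean norm,

    x_i ← (x_i − x̄_i) / ‖x_i − x̄_i‖₂ .

With this convention the Gram matrix S = XᵀX is exactly the Pearson
correlation matrix, and S is also the unique minimizer of the quadratic
matrix objective ‖W − XᵀX‖²_F. That optimization view is the core of the
package: priors on network structure enter as regularizers,

    min_W ‖W − XᵀX‖²_F + λ·R(W).

Two instantiations are implemented, alongside two baselines:

* **`pearson_network`** — W = XᵀX (λ = 0).
* **`hard_threshold_network`** — classical sparsification; keeps the p%
  strongest off-diagonal pairs. Ranking is by |W_ij| so that strong
  negative correlations survive; a literal signed variant
  (`ranking="signed"`, which discards all negative edges) is kept for
  comparability. Ties break lexicographically by (i, j) for determinism.
* **`estimate_pc_sparsity`** — R(W) = ‖W‖₁. The problem is separable, so
  the exact solution is elementwise soft thresholding, soft(S, λ/2).
  The solver is a proximal-gradient (ISTA) loop whose fixed point is that
  closed form; at the default step α = 1/2 it lands on it in one step. A
  `legacy_prox` flag applies the shrinkage with parameter λ instead of
  α·λ per iteration, reproducing a common loosely-written form of the
  algorithm whose fixed point is soft(S, λ) — i.e. a λ-rescaling; since λ
  is grid-searched downstream, the two forms explore the same family.
* **`estimate_pc_scale_free`** — R(W) = Σ γ_ij|W_ij| with degree-dependent
  weights updated by alternation (below).
* **`estimate_sr`** — sparse representation,
  min ‖X − XW‖²_F + λ‖W‖₁ s.t. diag(W) = 0, a partial-correlation-style
  baseline. Solved by ISTA with step 1/(2‖XᵀX‖₂) (one over the gradient's
  Lipschitz constant), diagonal re-projected to zero after each proximal
  step, objective verified non-increasing. The raw coefficient matrix is
  asymmetric; it is symmetrized as (W+Wᵀ)/2 by default (flag available)
  because all downstream consumers assume symmetry.

Estimators return the raw minimizer including its diagonal. Every
downstream consumer — feature extraction, degrees, s-metric, edge-list
export, threshold ranking — ignores the diagonal, so self-connections never
enter any statistic. This keeps the solver outputs exactly equal to their
closed forms, which the test suite exploits heavily.

## The degree-reweighted ("scale-free") estimator, and a caveat

The weighted penalty is meant to encode a scale-free prior: brain networks
tend to concentrate edges on a few hub nodes, so edges touching hubs should
be shrunk less. The weights are built from the previous iterate's weighted
degrees d_i = Σ_{z≠i}|W_iz| as

    γ_ij = exp(−(1/(d_i+ε) + 1/(d_j+ε))),   ε = 10⁻⁴,

and the alternation is: initialize γ ≡ 1; repeat
{ W ← weighted_soft_threshold(S, λ/2, Γ); Γ ← γ(W) } until the relative
Frobenius change of W falls below tol (1e-6) or 50 outer iterations.

**Caveat (empirically characterized, and the reason for `gamma_mode`):**
the exponential form above is *increasing* in degree — γ → 1 for strongly
connected nodes and γ → 0 (by underflow of exp(−2/ε)) for isolated nodes.
Multiplying the threshold by γ therefore shrinks hub edges *more* and
leaves edges of denuded nodes unshrunk. Two consequences, both reproduced
deterministically by the test suite on hub-structured synthetic cohorts:

1. Where the alternation converges (small-to-moderate λ), degrees are
   *homogenized*: at matched edge count the reweighted network has a
   *lower* s-metric than uniform shrinkage, and the pooled degree tail
   does not fatten as λ grows.
2. At larger λ the γ-underflow creates a persistent 2-cycle (nodes lose
   all edges → γ → 0 → their whole row returns → degrees jump → the row
   is re-shrunk). The returned last iterate then depends on the parity of
   the iteration cap and is flagged `converged=False`.

`gamma_mode="inverse"` uses the complement, γ' = 1 − γ, which is
*decreasing* in degree — the relationship the prior's description calls
for (hub edges shrunk less). It stays in (0, 1), needs no extra
parameters, converges at all tested λ, and robustly produces
hub-concentrated networks: on hub-topology cohorts (n=116, t=170) it beats
uniform shrinkage on the s-metric at matched edge count in 20/20 seeded
replicates at λ ∈ {0.2, 0.3}, and its pooled degree-tail mass at ≥2× mean
degree grows with λ. The default remains `"direct"` (the formula as
defined); the acceptance tests that assert hub concentration for the
default therefore fail, by design, and their messages point here.

## Graph diagnostics

* **Degrees** — binary (support count, |W_ij| > 1e-12) or weighted
  (Σ_{z≠i}|W_iz|); diagonal always excluded.
* **s-metric** — S(W) = Σ_{(i,j)∈E, i<j} d_i·d_j with binary degrees on
  the support, each unordered edge counted once. Among graphs with equal
  edge count, hub-concentrated wiring scores higher (star > path), which
  is why comparisons are made *at matched edge count*.
* **Degree cCDF** — P(D ≥ d) (weak inequality, the standard convention),
  pooled over subjects; zero-degree nodes are kept in the counts but
  dropped from the log-log export table since log 0 is undefined.
* **`match_edge_count`** — the edge count of soft(S, λ/2) is
  non-increasing and piecewise-constant in λ, so bisection (200 halvings)
  finds the largest λ whose count is ≥ the reference; ties among |S_ij|
  can make an exact match unattainable, so the achieved count is returned
  alongside.

## Classification pipeline

Per subject and per candidate regularization value, a network is estimated
and its strictly-upper triangle vectorized (n(n−1)/2 features; 6670 at
n=116). Evaluation is nested leave-one-out (LOO):

* outer LOO over subjects; inside each outer training set, an inner LOO
  grid search picks the parameter with the best inner accuracy (ties go
  to the smallest value, deterministically);
* feature selection is a two-sample two-tailed pooled-variance t-test at
  p < 0.05 (Welch available via flag), recomputed *inside every training
  partition* — including every inner fold — so no held-out subject ever
  influences the model that predicts it. Zero-variance features are
  dropped (undefined t); if nothing passes the threshold the single
  smallest-p feature is used so strong regularization cannot abort a fold;
* the classifier is a linear SVM with C = 1 and no additional feature
  scaling (correlations already live in [−1, 1]);
* predictions aggregate into confusion counts, reported as
  accuracy = (TP+TN)/N, sensitivity = TP/(TP+FN),
  specificity = TN/(TN+FP); a zero denominator yields NaN, never 0.

The inner loop uses a sufficient-statistics implementation of the pooled
t-test (class sums and sums of squares updated per left-out subject);
its p-values are asserted equal to `scipy.stats.ttest_ind` in the test
suite. `parameter_sweep` reports the LOO accuracy at each fixed grid
value (the accuracy-vs-parameter curve), reusing the same folds.

## Synthetic cohorts

The generator emulates the *shape* of a two-group resting-state ROI study,
not its physiology. Ground-truth networks are symmetric, zero-diagonal,
with weights uniform in ±[0.2, 0.8]: either uniformly random support at a
given density, or "hub" topology in which pairs touching one of
`hub_count` designated hubs get a boosted edge probability (multiplier 4
by default, base probability deflated to preserve overall density).
Subjects are drawn i.i.d. in time from N(0, Σ) with Σ = W_true + δI, δ
chosen so the smallest eigenvalue of Σ is ≥ 0.1, plus independent
N(0, noise_sd²) observation noise; the implied population correlation is
available in closed form and serves as the oracle in generator tests. An
AR(1) option (preserving the stationary covariance) exists but is off by
default — every estimator here is a function of the sample covariance
only, so serial dependence adds realism without adding test power.

Two-group cohorts add `effect` to a known random set of differential edges
in the positive group's W_true. Both groups share one diagonal loading δ
(the larger of the two groups' requirements) so the systematic group
difference is confined to the injected edges; if the required δ exceeds
10, the injected effect is deemed to have broken positive definiteness
beyond reasonable re-conditioning and an error is raised.

Default study conditions: n=116 ROIs, t=170 time points, 45 positive / 47
negative subjects, hub topology with 8 hubs, density 0.05, noise sd 0.2,
30 differential edges.

What passing tests on these cohorts do **not** show: performance on real
BOLD data. Because W_true must be diagonally loaded for positive
definiteness, synthetic population correlations top out near 0.26 —
substantially weaker than real resting-state correlation matrices, where
values up to ~0.8 are common. A fixed λ therefore does not transport
between the two scales: thresholds that leave a real correlation matrix at
intermediate density can empty (or, through the 2-cycle above, saturate)
a synthetic one. Tests choose λ values meaningful on the synthetic scale
and compare estimators at matched edge counts where possible. Site
effects, head motion, hemodynamics and non-Gaussian noise are out of
scope.

## Numerical choices

* Convergence: relative Frobenius change < 1e-6; 1000 inner iterations,
  50 outer (γ) iterations; non-convergence returns the last iterate with
  `converged=False` and a warning rather than raising.
* "Nonzero edge" means |W_ij| > 1e-12 everywhere (proximal solutions give
  exact zeros; text round-trips leave float dust). Text output uses 10
  significant digits, which round-trips at test tolerances.
* Degenerate (constant) ROI columns: standardization errors by default,
  naming the ROI; a `zero` policy maps them to zero columns with a
  warning. Silent zeroing would invisibly shift feature ranks.
* Hard-threshold pair count k = round(p/100 · n(n−1)/2).
* All randomness flows through numpy `default_rng` seeds; cohorts spawn
  per-subject seeds from a `SeedSequence`, so outputs are pure functions
  of (seed, parameters).

## Problem sizes used in the checks

The calibration checks run the full nested LOO at study scale (92
subjects × 6670 features) over a 4-point λ grid {0.2, 0.4, 0.6, 0.8} —
the grid is coarser than the 20-point screening grid the CLI defaults to,
which keeps the double-LOO loop (92 outer × 91 inner folds per grid
point) to a few minutes while still exercising the model-selection path.
Hub-concentration checks use 10–20 independent single-subject replicates;
support-recovery uses t=4000, n=20 so that sampling error (≈1/√t) sits
well below the weakest true edge.

## Known limitations

* The degree-reweighted estimator in its defined (`direct`) form does not
  achieve its stated goal of hub preservation; use `gamma_mode="inverse"`
  for that behavior (details above).
* The SR baseline's symmetrization is a post-hoc projection, not part of
  its optimization problem.
* `match_edge_count` targets the L1-shrunk estimator only; matching for
  other estimators reduces to the hard threshold's explicit pair count.
* The t-test/SVM pipeline is deliberately minimal (single univariate
  filter, fixed C); it is an evaluation harness for comparing network
  estimators, not a tuned classifier.
* LOO accuracy on a cohort with no true group difference is a noisy and
  pessimistically biased estimate of chance: leaving a subject out shifts
  its own class's training mean away from it, and with selected-by-chance
  features the classifier becomes anti-correlated with the held-out label
  (the well-known leave-one-out "anti-learning" effect). Null accuracies
  from single cohorts therefore scatter widely around — and below — 0.5.
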