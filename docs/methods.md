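# Methods

## Model

GeM-LR is a latent probabilistic graph model Z → X → Y for binary
outcomes. A categorical label Z with priors π₁…π_C selects a Gaussian
component N(μ_c, Σ_c) over the *gate* features X_G and a logistic
regression P(Y=1|x, Z=c) = σ(β_c′x_L + β_c0) over the *classifier*
features X_L. Gate and classifier feature sets may differ: the gate is
usually kept low-dimensional for covariance stability (e.g., restricted
to the top-variance features), while the classifiers may add covariates
such as study indicators that carry no Gaussian structure. Marginally
over Z the feature model is an ordinary Gaussian mixture; predictively
the model is a mixture of experts whose weights are the gate posterior
P(Z=c|x_G) ∝ π_c N(x_G|μ_c, Σ_c). Soft prediction takes the
posterior-weighted average of the expert probabilities; hard prediction
takes the argmax-posterior cluster's expert (ties to the lowest index).

## Estimation

Z is treated as missing data and the penalized observed-data log
likelihood

  L = Σ_i log Σ_c π_c N(x_i^G|μ_c,Σ_c) P(y_i|x_i^L,c) − R(β₁:C),
  R = Σ_c λ₁ Σ_j ((1−λ₂)/2 β²_{c,j} + λ₂|β_{c,j}|)

is maximized by EM:

* **Initialization.** Conventional unsupervised GMM fitting on X_G alone
  (k-means-seeded EM, best of `n_init` = 5 restarts), without the
  outcome. The initial heads are fitted to the unsupervised posterior
  weights. Initialization is independent per C.
* **E-step.** Responsibilities include the outcome likelihood:
  r_ic ∝ π_c N(x_i^G|μ_c,Σ_c) P(y_i|x_i^L,c). This is what makes the
  clustering *predictive* rather than purely geometric.
* **M-step, gate.** Weighted mixture updates: π_c = Σ_i r_ic / n, μ_c
  the r-weighted mean, Σ_c the r-weighted scatter about μ_c. Optional
  regularization follows: shrinkage Σ ← (1−α)Σ + α·diag(Σ) (α ∈ [0,1);
  0.9 is the documented small-sample preset), structures
  full/diagonal/tied/tied-diagonal (tied structures pool one covariance
  across components), and an eigenvalue floor at 1e-6 of the mean
  gate-feature variance as a degeneracy guard.
* **M-step, heads.** One elastic-net logistic regression per cluster on
  *all* points with observation weights r_ic (times any sampling
  weights), intercept unpenalized. A single λ₁ applies to every cluster
  (same sparsity level across clusters; the penalty is not rescaled by
  effective cluster size). Clusters with effective size below
  `min_cluster_ess` (default |L|+1) or whose weighted outcome is
  single-class get a frequency head: the r-weighted class-1 frequency
  clipped to [1e-3, 1−1e-3].

Because the complete-data objective separates into a gate block and a
head block, each exact M-step increases the penalized observed-data
objective; the run records the objective trace and the non-decrease is
tested (tolerance 1e-8 per step for full covariance without shrinkage;
shrinkage/tied adjustments may cost a bounded 1e-6 per step).
Convergence is declared at relative objective change < 1e-6, with
`max_iter` = 500. If a cluster's effective size falls below 2, that C is
infeasible; the error reports the largest feasible C (found by retrying
smaller values). All mixture arithmetic is in the log domain with
log-sum-exp.

The weighted elastic-net fits use scikit-learn's saga solver (C = 1/λ₁,
l1_ratio = λ₂, fixed shuffle seed for reproducibility of the convex
optimum). saga's stopping rule watches only the coefficients, so a 1-D
Newton polish of the unpenalized intercept at fixed coefficients is
applied afterwards; this is coordinate ascent and preserves monotonicity.
First-order optimality is verified by the elastic-net KKT conditions
(|gradient| ≤ λ₁λ₂ for zeroed coefficients).

## Cluster annotation

For a feature subset h, the implied marginal mixture is obtained by
restricting means and covariances to h. With x drawn from cluster c's
marginal, the expected share of mixture mass claimed by cluster c is a
ratio of expectations with closed form via the Gaussian product
integral O(s,t) = ∫N(x|μ_s,Σ_s)N(x|μ_t,Σ_t)dx = N(μ_s|μ_t, Σ_s+Σ_t):

  τ_c+(h) = π_c O(c,c) / Σ_s π_s O(c,s)
  τ_c−(h) = π_c Σ_{s≠c} π_s O(c,s) / Σ_{s≠c} π_s Σ_t π_t O(s,t)

(the complement-mixture normalizations 1/(1−π_c) cancel), combined as
A_c(h) = π_c τ_c+ + (1−π_c)(1−τ_c−) ∈ [0,1]. The ratio-of-expectations
form is the one that admits these closed forms; both are verified
against ratio-of-means Monte Carlo in the test suite. When all
components coincide, τ_c± = π_c and A_c = π_c² + (1−π_c)² exactly; A_c
is defined as 1 for C = 1.

Forward selection greedily adds the feature maximizing A_c(h∪{j}) (ties
to the lowest index), always selecting at least one feature, and stops
when the best available gain is below `delta_stop` = 0.1 **and**
|A_c(h) − A_c(G)| < `gap_stop` = 0.01 (both configurable; an optional
A-target stop is available). For p ≤ 4 the greedy trace is checked
against exhaustive 2^p enumeration. Backward elimination is not
implemented.

## Evaluation and tuning

Stratified K-fold CV (default K = 5; stratification balances classes
within one per fold) with per-fold AUCs averaged — per-fold averaging,
not score pooling — and repeats averaged over re-randomized folds and
EM seeds. The AUC is the Mann–Whitney statistic with ties counted one
half, optionally with importance weights w_i w_j on (positive, negative)
pairs. Standardization (centering/scaling by training statistics;
constant columns centered only) is refit inside every fold on the
training rows alone. The 95% CI uses the influence-curve variance of the
cross-validated AUC: φ = y/p₁(F₀(s)−AUC) + (1−y)/p₀(S₁(s)−AUC) per
held-out observation, fold variances mean(φ²)/n_k pooled across folds
(repeats treated as independent — an approximation that understates the
correlation between repeats).

Tuning is non-nested, as appropriate for small samples: λ₂ = 0.8 fixed;
λ₁ chosen by CV on the entire data over a 20-point log grid spanning
four decades down from λ_max (the KKT threshold at which the C=1
solution is fully sparse), ties to the larger λ₁; the cluster count by
CV over a user grid, infeasible values excluded, ties to the smaller C.
A paired two-sided t-test over per-repeat CV AUCs compares methods on a
shared fold plan. Two-phase designs are handled by inverse-probability
oversampling of training rows (each row replicated round(1/p_i) times
with seeded stochastic rounding) and inverse-probability-weighted AUC on
held-out rows; weighted fitting via `FitConfig.sample_weights`
(responsibilities multiplied in both M-steps) is the alternative path.

## Baselines

Cluster-then-predict (CP): k-means (k-means++, best of 5 restarts) on
the standardized gate features, then an independent elastic-net logistic
regression per cluster using only that cluster's points, with the same
λ and the same frequency-fallback rule; test points are assigned to the
nearest centroid (Euclidean, ties to the lowest index). With C = 1, CP,
plain elastic-net LR and GeM-LR coincide — verified to 1e-6 against a
directly fitted reference. KNN/random-forest/neural baselines are out of
scope (off-the-shelf elsewhere).

## Synthetic data

The generators sample the model's own graph: Z ~ Categorical(π),
X_G|Z ~ N(μ_Z, Σ_Z), independent N(0,1) noise features, optional
Bernoulli(1/2) binary covariates entering only the classifiers, and
Y|X,Z ~ Bernoulli(σ(β_Z′x_L + β_Z0)). Presets:

* `heterogeneous` — C=2, π=(.5,.5), gate means ±3 per coordinate,
  identity covariances, opposite-sign β of magnitude 2 with intercepts
  β_c0 = −β_c′μ_c so outcomes are mixed within clusters; the pooled
  feature–outcome association cancels (|r| ≈ 0) while within-cluster
  associations are strong (|r| ≥ 0.4). n defaults to 200.
* `homogeneous` — the same two-cluster geometry along g1 with one
  shared moderate effect (β = 1.0) on g2, orthogonal to the cluster
  separation: cluster structure without predictive heterogeneity
  (within-cluster AUC ≈ 0.75, the regime typical of vaccine-trial
  panels).
* `small_highdim` — n = 72, an 18-feature correlated panel plus one
  binary covariate, three clusters expressed in five
  inflated-variance coordinates; intended for gate-restriction
  (top-variance screening) pipelines.
* `null` — one cluster, β = 0.

Deterministic given the scenario seed; truth records carry labels and
all parameters. `recovery_report` scores a fit by adjusted Rand index of
hard assignments, worst-case mean/prior errors after optimal label
matching (Hungarian assignment on the confusion matrix; fitted
parameters mapped back to the raw scale through the standardizer), and
the fraction of truly nonzero coefficients recovered with the correct
sign (signs are invariant to positive rescaling, so standardization does
not affect them).

What the generators do *not* emulate: assay-specific noise and detection
floors, missingness (inputs must be complete; imputation is upstream),
non-Gaussian cluster shapes, and confounding structures. Passing tests
on these presets therefore demonstrates correctness of the machinery and
the model's behavior *within its own assumptions*, not robustness to
real-data violations of them.

A structural observation from the comparative experiments: when clusters
are well separated, responsibilities are effectively one-hot and
GeM-LR's weighted per-cluster fits coincide with CP's subset fits, so
the two methods tie; GeM-LR's advantage over CP emerges only when the
gating structure is soft (overlapping or continuous gating variables),
whereas its advantage over a single pooled model is large whenever the
cluster-wise associations genuinely differ. The test suite asserts the
latter (margin ≈ 0.4 AUC on the heterogeneous preset) and documents the
former.

## Numerical choices and conventions

Cluster indices are 0-based in the API and 1-based in CLI/report output.
Ties: hard assignment and centroid assignment to the lowest index;
greedy selection to the lowest feature index; λ₁ to the sparser, C to
the smaller. Degenerate-variance features get scale 1 (centering only).
Frequency heads are clipped to [1e-3, 1−1e-3] for finite log loss. The
variance floor is 1e-6 of the mean gate-feature variance. All
randomness derives from one top-level seed via named substreams
(initialization, folds, oversampling, simulation), keeping every derived
seed below 2³¹. Problem sizes in the packaged checks (n = 150–500,
5–10 replicate seeds, 2×10⁵ Monte Carlo draws) were chosen to make the
statistical assertions stable at interactive runtimes.

## Known limitations

* Row order affects iterative solvers at the optimizer-tolerance level;
  CV results are invariant to row order only up to ~1e-3 in AUC.
* The repeats-as-independent CI pooling is anti-conservative for many
  repeats.
* No multi-task coupling of coefficients across clusters; each head is
  penalized independently.
* Multiclass/continuous outcomes and survival endpoints are out of
  scope, as is plotting (reports are tabular).
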