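# Methods

## Model

For genome *i* = 1, …, n let Y_i indicate that the gene of interest was
*observed*, X_i ∈ R^p its covariates (first entry 1), and M_i ∈ R^q its
genome-quality variables.  A latent indicator λ_i marks *true* presence:

    logit Pr(λ_i = 1 | X_i) = X_i' β                        (presence)
    Pr(Y_i = 1 | λ_i = 1, M_i) = f(M_i)                     (detection)
    Pr(Y_i = 1 | λ_i = 0)      = ε                          (contamination)

with λ_i and Y_i conditionally independent Bernoulli draws.  β_k is the
difference in log-odds of true presence per unit of X_k, holding the other
covariates fixed — the estimand of scientific interest.  The detection
curve f is constrained to be monotone non-decreasing in genome quality:
better-covered, more complete genomes cannot be *less* likely to reveal a
present gene.  ε is the probability that an absent gene is nonetheless
observed (contamination, index switching); ε and f are not jointly
identifiable, so ε is a fixed hyperparameter, never estimated.  Sensible
choices: 0 for carefully refined MAGs, or the maximum CheckM contamination
observed in the cohort; `epsilon_sensitivity` re-runs a test over a grid
(e.g. 0, 0.01, 0.05, 0.1) to check robustness.

The observed-data log-likelihood marginalises λ_i:

    L(θ) = Σ_{i: y=0} log[ (1 − ε + (1 − f(M_i)) e^{X_i'β}) / (1 + e^{X_i'β}) ]
         + Σ_{i: y=1} log[ (ε + f(M_i) e^{X_i'β}) / (1 + e^{X_i'β}) ].

## Estimation

θ = (β, f) is estimated by EM on the expected complete-data log-likelihood,
penalized by the Firth/Jeffreys term ½ log |Σ_i X_i X_i' w_i(1 − w_i)|,
w_i = expit(X_i'β), which guarantees finite β̂ under separation — a common
occurrence for accessory genes in small cohorts.

- **E-step.**  p_i = Pr(λ_i = 1 | Y_i, θ) by Bayes' rule.  With ε = 0 a
  detection cannot be contamination, so Y_i = 1 forces p_i = 1 exactly;
  before the M-steps p is clipped to [1e−10, 1 − 1e−10] for numerical
  stability of the weighted logistic fits.
- **M-step for β.**  Firth-penalized logistic regression with fractional
  outcomes p_i: Newton scoring on the Firth-adjusted score with
  step-halving, to gradient norm 1e−8 (cap 100 iterations).  For
  null-constrained fits (below) the penalty uses the reduced design.
- **M-step for f.**  Two monotone classes:
  - *I-spline* (default): f̃ = logit f = α₀ + Σ_j α_j I_j(M) with α_j ≥ 0.
    The basis functions I_j are exact integrals of clamped B-splines
    (piecewise polynomial, each rising 0 → 1 over the observed quality
    range), so non-negative combinations are non-decreasing.  The weighted
    Bernoulli log-likelihood Σ p_i [Y_i f̃_i − log(1 + e^{f̃_i})] is
    maximised by a projected-Newton active-set iteration on the box
    constraints, with an L-BFGS-B fallback and a guaranteed
    at-least-constant-fit result.
  - *Isotonic*: f̃ is a non-decreasing step function on the observed
    quality values, fitted by pool-adjacent-violators over the same
    weighted Bernoulli loss plus a penalty −cosh((f̃_i/a)²), a = 50, which
    keeps the logits bounded when a block contains only detections or only
    non-detections.  Each pooled block value solves a one-dimensional
    penalized score equation by bracketed root finding; ties in M share a
    value.
- **Stopping.**  The monitored quantity is the *penalized* observed-data
  log-likelihood.  Iteration stops at `t_max` (default 1000) or once the
  relative increase (ℓ_t − ℓ_{t−1}) / (|ℓ_{t−1}| + 1e−12) has been below
  `delta` for 5 consecutive iterations, with a floor of 16 iterations.
  `delta = 0.01` suits large cohorts with asymptotic testing;
  `delta = 0.1` is the small-cohort / permutation setting, trading a small
  amount of optimisation accuracy for the B-fold cost of permutation.

Degenerate genes (all-zero or all-one Y with ε = 0) produce a flagged
non-identified fit: β at its Firth-stabilised value, the curve at its
boundary, rather than an error.

### Numerical choices

- Detection-curve logits are hard-capped at ±10 when evaluated
  (probabilities within [4.5e−5, 1 − 4.5e−5]); the cosh penalty already
  bounds the isotonic class, the cap gives the I-spline class the same
  protection.  Outside the observed quality range curves extrapolate as
  constants, preserving monotonicity and bounds.
- I-spline defaults: 4 basis functions of degree 3.  `spline_df` is the
  number of monotone basis columns; `df − degree − 1` interior knots are
  placed at quantiles of the distinct observed quality values (none at the
  default, giving a clamped integrated-Bernstein basis).  Small cohorts —
  the target application — do not support more flexibility.
- Only q = 1 quality variable is supported for the nonparametric curves
  (as in all analyses this model was designed for); for q ≥ 2 a logit-linear
  curve with non-negative slopes is available (`f_class="linear"`).

## Hypothesis testing

Linear null hypotheses Aβ = c (rank(A) = h) are fitted by
reparameterising β = β₀ + Nγ, with β₀ a least-squares particular solution
and N a null-space basis of A, and running the same EM on the reduced
design XN with offset Xβ₀.  The test statistic is
Q = 2[L(θ̂) − L(θ̂₀)] on the *unpenalized* observed-data log-likelihood
(the Firth penalty is an estimation device, not part of the evidence), and
is floored at zero.  Because the alternative and null fits carry different
penalties (full vs reduced design), the raw difference can be slightly
negative — ~0.05 under the loose `delta = 0.1` stopping rule — which the
floor absorbs; the alternative is also warm-restarted from the null
optimum whenever the ordering is violated, and a violation beyond 2.0
raises an optimiser-failure error.

- **Asymptotic (happi-a).**  p = Pr(χ²_h ≥ Q).  Reliable for large n
  (~100 genomes); anti-conservative below that.
- **Permutation (happi-np).**  The tested covariate columns of X are
  permuted jointly across genomes, holding Y, M and the untested columns
  fixed — under the null the tested covariates are exchangeable with
  respect to (Y, M) — and Q is recomputed per permutation with fits
  warm-started from the observed optima.  p = (1 + #{Q_b ≥ Q₀}) / (B + 1),
  never below 1/(B+1); B ≥ 19 is required to resolve the 5% level, and
  B = 1000 is the default for real analyses.  Given a seed the procedure
  is bit-reproducible.

Across genes, Benjamini–Hochberg q-values are computed within each method.
The whole-matrix workflow spawns per-gene permutation seeds from a single
root seed, so results are independent of gene ordering and parallelism.

## Baselines

`glm_lrt` and `glm_rao` are ordinary (unpenalized) logistic-regression
tests of the *observed* indicator, matching standard GLM software; the Rao
score form is the procedure used for pangenome enrichment in popular
multi-omics platforms.  They ignore M by definition.  Separation is
detected and flagged, and the statistic is then computed from a
coefficient-capped (|β| ≤ 15) fit rather than silently "fixed".  On 2×2
layouts the Rao statistic equals the Pearson chi-square, a useful exact
check.

## Simulation framework

`simulate_dataset` draws from the model itself under the study design used
throughout validation: a deterministic coverage grid
M_i = 10 + 30(i−1)/(n−1) (10–40×), covariate X_{i2} ~ N((i−1)/(n−1), σₓ)
so that smaller σₓ means stronger coverage–covariate correlation (the
regime where quality-naive tests fail), intercept X_{i1} = 1, ε = 0, and a
monotone surrogate detection curve

    f(m) = expit(−2 + 0.3 m),

≈0.12 at zero coverage, ≈0.73 at the grid's lowest coverage and
essentially 1 beyond 30× — the rising shape seen when genes are called on
reads subsampled to increasing depth.  Defaults for the study harnesses
follow the validation design: n ∈ {30, 50, 100}, σₓ ∈ {0.25, 0.5},
β₁ ∈ {0.5, 1, 2}, 500 replicates (250 for the curve-class comparison),
B = 1000, `delta = 0.1`, minimum 16 EM iterations.  Rejection rates are
reported with 95% Wald binomial intervals.

What the generator does *not* emulate: an empirically calibrated detection
curve.  The surrogate is steep and near-saturated across most of the
10–40× grid, so the *magnitude* of the quality-naive GLM's
anti-conservativeness is muted at large n compared with what sharper
empirical curves produce — with this surrogate, GLM-LRT inflation is
driven mostly by the small-sample chi-square approximation (≈9% at n = 30)
and is mild at n = 100.  The permutation test's nominal type-1 control,
the asymptotic test's large-n calibration, and the efficiency ordering of
the two curve classes are robust to the curve choice and are the primary
validation targets.  Real data also feature quality variables beyond
coverage, non-Bernoulli contamination, and between-genome dependence
(shared assembly pipelines, phylogeny), none of which the generator
models; passing simulations demonstrate correctness of the inference
machinery under the stated model, not robustness to those violations.

Test-suite scales: the permutation type-1 check runs 120 replicates at
B = 99, the asymptotic and GLM checks 500 replicates, parameter recovery
250 replicates — sizes chosen so the full suite completes comfortably on a
single CPU while keeping Monte-Carlo error small relative to the asserted
bands.

## Known limitations

- ε is assumed known; misspecifying it biases β̂ (use the sensitivity
  sweep).
- Monotone detection can be misspecified, e.g. extremely deep short-read
  sequencing can *hurt* assembly of repetitive regions; the model offers
  no diagnostic for this.
- Genes are modelled independently; no joint or phylogenetic modelling.
- The asymptotic test should not be trusted below roughly 100 genomes —
  use the permutation test there (at B-fold cost).
- No confidence intervals for β are provided, only tests.
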