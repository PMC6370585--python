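# Methods

## Model

NRLMF factorizes the binary drug–target adjacency `Y` (nd × nt) through
a logistic link: each drug *i* and target *j* carry latent vectors
*u_i*, *v_j* ∈ ℝ^r and interact with probability
σ(*u_i*ᵀ*v_j*). Three modelling choices shape the estimate:

1. **Importance weighting.** Observed interactions are experimentally
   confirmed; zeros are merely unknown. The likelihood therefore counts
   each observed pair *c* times (weight `1 + c·y − y` on the log-loss),
   biasing the fit toward not explaining away confirmed interactions.
2. **Gaussian priors.** Latents get zero-mean isotropic priors with
   precisions λ_d, λ_t, giving ridge terms (λ/2)‖·‖²_F.
3. **Neighborhood regularization.** For each entity, the K₁ most
   similar entities (by the corresponding similarity matrix row, self
   excluded) define a directed weighted graph with adjacency
   `A[i,l] = S[i,l]`. Its Laplacian `L = (D + D̃) − (A + Aᵀ)` (D, D̃ the
   row/column-sum diagonals) satisfies
   tr(XᵀLX) = Σ_{i,l} A[i,l]·‖x_i − x_l‖², so the penalties
   (α/2)tr(UᵀL_dU) and (β/2)tr(VᵀL_tV) pull similar entities' latents
   together — the "similar drugs bind similar targets" premise.

The MAP objective is minimized by alternating AdaGrad: one full update
of U holding V, then V holding the updated U, with per-coordinate steps
θ·g/√(G + 1e−8) where G accumulates squared gradients. The objective is
recorded once per round; AdaGrad is not per-step monotone, so only the
overall decrease is asserted in tests. A non-finite objective aborts
with a diagnostic naming the iteration (the signature of a divergent
θ).

**Cold-start smoothing.** After fitting, each entity with no observed
interaction (a "negative" drug/target) has its latent vector replaced
by the similarity-weighted average of its K₂ most similar *positive*
entities. If every selected similarity is zero the row is kept
unsmoothed with a warning — this is precisely the failure mode the beta
rescoring targets, so the core model does not invent a remedy.
Prediction scores are σ(*ũ_i*ᵀ*ṽ_j*).

## Beta rescoring

The score *s* is reinterpreted as the mode of a bell-shaped beta
distribution (a, b > 1) whose concentration a + b = γ·η₁ + η₂ encodes
the pair's evidence: γ is the row-plus-column sum of the *training*
adjacency (an interacting pair's own entry is counted in both sums, as
the definition states). Solving mode and concentration for (a, b) and
reporting the mean a/(a+b) gives the closed form

    s' = (s·(γ·η₁ + η₂ − 2) + 1) / (γ·η₁ + η₂).

Properties asserted by tests: strict shrinkage toward ½ at finite
concentration; monotonicity in *s* at fixed γ (so within a γ-stratum
the ranking is preserved); s' increasing in γ for s > ½ and decreasing
for s < ½; and s' → s as η₁ → ∞ (for γ ≥ 1). η₂ > 2 is required so
both beta shapes exceed 1. γ is always computed from the training
matrix with held-out entries zeroed — using the full matrix would leak
test labels into the evidence counts.

## Evaluation protocol

Three repeated 10-fold cross-validation scenarios: CVS1 partitions all
nd·nt pairs, CVS2 partitions drugs (test folds are whole rows), CVS3
partitions targets (whole columns); fold sizes differ by at most one
unit and each repetition reshuffles with seed `base_seed + repetition`.
Training data is the adjacency with test entries zeroed; evaluation
computes AUC (Mann–Whitney, ties ½) and AUPR (step-wise,
non-interpolated — linear PR interpolation is known to be optimistic)
over the test pairs against the true labels, unknowns as negatives.
Folds whose test labels are single-class yield NaN metrics and are
excluded from that repetition's mean with a warning (plausible on
very small datasets). Summary statistics are the mean of the
per-repetition means and a 95% Student-t half-width over those means
(df = repetitions − 1; NaN for a single repetition). The
repetition-level CI was chosen over a fold-level CI because folds
within a repetition share one shuffle and are not independent.

Nested (external) validation selects hyperparameters per outer fold by
inner pair-wise (CVS1) cross-validation run entirely on the
outer-training adjacency — outer test entries are zeroed before the
inner split is drawn, so selection can never read held-out labels — and
evaluates the winner once on the outer fold.

All randomness flows from user-supplied integer seeds through
`numpy.random.default_rng`; per-fold fit seeds are derived by a fixed
affine map kept below 2³¹, making every pipeline byte-reproducible.

## Hyperparameter search

An outer exhaustive sweep over log₂-spaced grids (defaults: r ∈ {50,
100}, α ∈ 2^{−5..2}, β ∈ 2^{−5..0}, λ_d = λ_t ∈ 2^{−5..1}, θ ∈
2^{−3..0}, η₁ ∈ 2^{5..9}, η₂ ∈ 2^{2..5}, c = 5, K₁ = K₂ = 5) is
combined with inner Bayesian optimization of the tied prior precision λ
and the drug Laplacian weight α on each fixed slice. The optimizer is
GP-MI: a squared-exponential Gaussian-process surrogate over
log₂-transformed coordinates (length scale = median pairwise candidate
distance, observation noise 1e−8 so the posterior mean interpolates
observations to ~1e−6) picks the candidate maximizing
μ(x) + √ln(2/δ)·(√(σ²(x)+γ̂) − √γ̂), where γ̂ accumulates the selected
predictive variances and δ = 1e−100. Acquisition ties are broken by a
seeded draw; candidates are never re-evaluated, so a budget equal to
the grid size degenerates to exhaustive search (asserted in tests). The
default budget is 15 evaluations per (λ, α) plane (≤ 56 points). The
kernel, noise and budget are this package's declared defaults; GP-MI
itself prescribes only the acquisition rule.

## Synthetic data

The generator emulates the structure the model assumes: latents drawn
from the model's own zero-mean Gaussian prior (default precision
0.125, matching the model's default λ — this reproduces the
near-ceiling pair-holdout separability the public gold-standard
benchmarks exhibit), a logistic intercept found by bisection so the
expected density matches the request within 10% relative, Bernoulli
sampling of `Y`, and Gaussian-kernel similarities computed *from the
same latents* (length scale = median pairwise latent distance), so the
neighborhood regularizer's premise holds by construction. Cold
drugs/targets are whole rows/columns zeroed *after* sampling —
unobserved, not truly non-interacting, matching the premise of the
whole-entity holdout scenarios.

What the generator does **not** emulate: real fingerprint/sequence
similarity distributions (heavy left tails, block structure), noisy or
misleading similarities, and the extreme degree skew of curated
interaction data (many singleton drugs). Consequences for
interpretation:

- Recovery results (held-out pair AUC ≈ 0.9 at 60 × 30, rank 5, 10%
  density) show the estimator works when its assumptions hold; they say
  nothing about misspecified similarities.
- Because similarities here are perfectly informative, cold-start
  smoothing works nearly as well as having the data, leaving the
  rescoring step nothing to fix: on this synthetic data rescoring does
  **not** improve whole-target-holdout AUPR. The regime where rescoring
  pays off is sparse real data with mean entity degree near 1, where a
  held-out column turns many drugs into zero-evidence (γ = 0) rows
  whose positives the raw model under-scores; at mean drug degree 3
  the γ = 0 stratum is instead dominated by genuinely non-interacting
  drugs, and lifting it floods the top ranks with negatives. The test
  suite states the favorable-direction expectation and reports its
  failure on this generator honestly rather than weakening it.

## Problem sizes and defaults

Library defaults: c = 5, K₁ = K₂ = 5, r = 50, λ_d = λ_t = 0.125,
α = β = 1.0, θ = 0.5, η₁ = 128, η₂ = 8, 100 AdaGrad rounds (no early
stopping — a fixed budget keeps runs deterministic and comparable; the
trace is exposed for inspection). α, β, λ and θ were chosen by a small
grid sweep of cross-validated AUC on synthetic data — the same
selection protocol the search module automates — and all lie inside the
standard search ranges. Initialization is seeded Gaussian with standard
deviation 1/√r, keeping initial logits O(1). Tests and the synthetic
benchmark use 8–60 drugs and 6–30 targets with r ≤ 5, where a full fit
takes ~20 ms and the entire suite runs in seconds; the method scales to
the public benchmarks (up to 445 drugs × 664 targets) unchanged.

Nearest-neighbor ties are broken toward the smallest index and self is
always excluded; similarity matrices are *not* symmetrized (neighbor
lookups read rows only, and real chemical-similarity scores can be
asymmetric). Similarity entries outside [0, 1] by ≤ 1e−9 are clamped;
larger violations are errors. Scores of exactly 0 or 1 are accepted by
the scalar rescoring utility (the closed form is defined there) even
though beta shapes require interior modes.

## Known limitations

- The rescoring direction result above: improvement claims are
  benchmark-regime-specific and not reproduced by this generator.
- AUPR via step-wise summation equals scikit-learn's average
  precision; published numbers computed with interpolated PR curves
  will differ slightly.
- The GP surrogate assumes a stationary kernel over log₂ coordinates;
  axes not log₂-spaced would need rescaling.
- `fit` materializes dense nd × nt probability matrices; fine for the
  benchmark family, not for very large interactomes.
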