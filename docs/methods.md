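# Methods

## Model

Drugs `a¹…aᵐ` and targets `b¹…bⁿ` are embedded as points `uⁱ, vʲ` on the
upper sheet of the hyperboloid H^d ⊂ R^{d,1} (curvature fixed at −1;
coordinates dimensionless; no curvature parameter is exposed).  The
probability of an interaction is a logistic link on the squared Lorentzian
distance,

    p_ij = σ(−d_L²(uⁱ, vʲ)),   d_L² = −2 − 2⟨·,·⟩_L = 2(cosh d_H − 1),

so p ∈ (0, 0.5], maximal for coincident points and strictly decreasing in
the geodesic distance.  Observations are confidence-weighted Bernoulli
draws: cells with r_ij = 1 get weight c ≥ 1, cells with r_ij = 0 (meaning
*no known* interaction) weight 1.  The prior on every latent row is the
wrapped normal G(μ₀, σ²I): a tangent Gaussian at the vertex pushed onto the
manifold by parallel transport and the exponential map.  Its log-density is

    ln p(z) = ln N(x̄ | 0, σ²I) − (d−1) ln( sinh r / r ),  r = d_H(μ₀, z),

with x̄ the tangent pre-image; the correction term is the volume distortion
of the exponential map.  The training loss is the negative log-posterior
with all embedding-independent constants dropped (so logged loss values are
comparable only within a run), with prior precision parametrized as
α = 1/(2σ²).  With similarity matrices S (drugs) and T (targets) the
neighborhood term β_U Σ_ij s_ij d_L²(uⁱ,uʲ) + β_V Σ_ij t_ij d_L²(vⁱ,vʲ) is
added; the diagonal contributes nothing and the full i,j grid is summed as
written.

## Optimization

Alternating full-batch Riemannian gradient descent: per epoch, every drug
row is updated with the targets fixed, then every target row with the
updated drugs.  A row update computes the ambient Lorentzian gradient
(vector of partials with the time-like component negated), projects it
orthogonally onto the tangent space, optionally rescales it to a maximum
Lorentzian norm (`clip_norm`, default 1.0 — the heuristic guard against the
gradient explosions hyperbolic descent suffers near cliffs), and moves with
the exponential map.  The learning rate is annealed over `phases` = 3
phases (`lr_decay` = 0.1 between phases), and every updated point is
re-projected onto the hyperboloid by recomputing its time-like coordinate
from the space-like ones — cheap, exact, and preserves the first d
coordinates.  Neighborhood-regularization gradients are derived from
∂d_L²(uⁱ,uʲ)/∂uⁱ_k = −2uʲ_k (k ≤ d) and +2uʲ_{d+1}, with the symmetrized
coefficients s̃_ij = s_ij + s_ji because uⁱ occupies both sum positions;
correctness rests on the central-finite-difference oracle in the test
suite, which covers c ∈ {1, 5}, α, β ∈ {0, >0} and d = 1 (where the (d−1)
prior term vanishes identically).

Two initializations are provided:

* **Random** (default): wrapped-normal draws at the vertex with
  `init_sigma2` = 0.01 — starting near the origin keeps the early steps in
  the flat, numerically benign region.
* **Similarity-seeded**: when a drug-similarity matrix is available, drugs
  are placed by Lorentzian MDS of the similarity-derived distances
  (d² = −τ ln s, with τ calibrated as the median squared pairwise distance
  of a prior sample at the model's own σ²) and targets at the Lorentz
  centroid of their interacting drugs (weighted profile over T for
  interaction-less targets).  The refinement then mostly calibrates scales
  instead of untangling points.  On planted data the random-init descent
  reliably reaches ~0.83 held-out AUC while the same objective started at
  the ground truth supports ~0.86; the similarity seed closes that basin
  gap (~0.88) and is the package's recommended start whenever similarities
  exist.

## Cold start

The latent vector of an entity with an empty interaction profile is the
weighted combination of its J (default 5) most similar neighbors' vectors,
computed as the Lorentz centroid: the minimizer of Σ w_k d_L²(x, p_k) over
H^d has the closed form m/√(−⟨m,m⟩_L) with m the weighted ambient mean.
The closed form is validated against a direct numerical Fréchet-mean
minimization in the tests — the numerical oracle, not the formula, is the
source of truth.  Positive-scale invariance of the closed form makes the
1/SM profile normalization immaterial (before or after hyperboloid
projection gives the same point).  In cross-validation, empty training
rows/columns are handled as follows: with the profile protocol enabled they
are rebuilt by the weighted profile; without similarities they fall back to
the vertex (origin/zero for the Euclidean baseline); with similarities but
profile rebuilding off, the fitted position is kept, since the neighborhood
regularizer and/or similarity-seeded start already placed it — empirically
the centroid rebuild *degrades* CVP ranking in that regime by crowding
imputed rows into dense areas.

## Euclidean baseline

A minimal neighborhood-regularized logistic MF: logits uᵀv, zero-mean
Gaussian priors α‖·‖², Euclidean neighborhood regularization
β Σ s_ij ‖uⁱ−uʲ‖², Euclidean weighted-profile cold-start, and the same
alternation/annealing/clipping schedule (clipping in Euclidean norm).  It
shares folds, metrics, and seeds with the hyperbolic model so all
comparisons are paired.

## Synthetic data

`generate_synthetic` draws both embeddings from G(μ₀, σ²I), samples
r_ij ~ Bernoulli(p_ij) from the model's own link, and derives similarities
with a Gaussian kernel on geodesic distance, s = exp(−d_H²/τ), τ = median
off-diagonal squared distance (the kernel is a generator choice, not part
of the model).  At the reference conditions (m = 60, n = 50, d_true = 3,
σ² = 1) the density is ~3% — Yamanishi-like sparsity — and the planted
probabilities achieve AUC ≈ 0.94 against their own draws, the Bayes
reference for recovery.  `generate_euclidean_synthetic` mirrors this for
the baseline (Gaussian factors, dot-product logits); its planted variance
defaults to σ² = 3 in the reference experiment so that the planted-oracle
AUC (~0.95) matches the hyperbolic experiment's — at σ² = 1 the Euclidean
oracle itself is only ~0.81, and a recovery experiment against a bar the
oracle cannot reach would test nothing.  `generate_tree_synthetic` embeds a
regular b-ary tree in H² with equal edge lengths (children fanned around
the circle of directions, avoiding the parent edge), drugs at leaves and
targets at internal nodes; the reference configuration is a binary tree of
depth 5 (32 leaves, 31 internal nodes) with edge length 0.5, which keeps
leaf–parent link probabilities near 0.44 and distant pairs near 0 — enough
signal for a meaningful low-rank comparison.  What the generators do *not*
emulate: measurement biases of real assays, hub-degree heterogeneity,
chemically derived similarity noise, and the unknown true geometry of real
drug–target space — passing recovery here shows the estimator works when
its assumptions hold, not that real data satisfy them.

## Evaluation

CVP pair k-fold: all m·n cells partitioned into k groups per round, each
hidden once; scores are pooled per round and each metric computed once per
round, aggregated as mean ± std (population std) across rounds.  Per-drug
LOOCV hides one drug's entire row per fold.  AUC is the tie-aware
Mann–Whitney statistic.  AUPR uses step-wise (right-continuous) PR
interpolation, which avoids the over-optimism of trapezoids; under this
convention the step-curve area coincides with average precision, and both
are reported for interface completeness.  PREC@10 is computed over the
pooled test cells of a round by default (a per-drug variant is available).
All ranking ties are broken by a fixed seeded order.  The benchmark runner
grid-searches each method with an inner single-round CV on a disjoint seed,
selecting by mean AUPR (the metric class preferred for sparse interaction
matrices), then evaluates the winner on the shared plan.

## Numerical choices

* arccosh arguments clamped to ≥ 1; sinh(t)/t, arccosh(a)/√(a²−1) and the
  prior-gradient factors evaluated by second-order series below thresholds
  (1e−6 for values, 1e−4 in r for gradients) where the closed forms are
  0/0.
* ln(sinh r / r) evaluated as r − ln 2r + ln(1 − e^{−2r}) for r > 20 to
  avoid overflow.
* Constraint and tangency assertions use absolute tolerance 1e−9 scaled by
  (1 + x_{d+1}²), since cancellation error in ⟨x,x⟩_L grows quadratically
  with the coordinates.
* The loss is a smooth function of the ambient coordinates (no clamping on
  the likelihood path), which both the optimizer's ambient gradients and
  the finite-difference checks require.
* Probabilities are computed through the stable sigmoid, so distant pairs
  underflow to 0 rather than overflowing.

## Reference experiments and problem sizes

`lorentzmf.experiments` fixes three desk-scale experiments (also run by
`scripts/acceptance.py`): hyperbolic planted recovery (5 datasets of
60×50, five-fold CVP, d = 3, c = 5, α = 0.5, β = 0.5 over 5-NN-sparsified
similarities, similarity-seeded init, η = 0.05, 3×20 epochs), Euclidean
planted recovery (same shape, σ² = 3, c = 1, α = 0.05, unclipped descent),
and the tree comparison (10 binary-tree datasets, both methods at d = 5 on
identical folds).  These sizes keep every experiment within seconds on a
single CPU while leaving the recovery thresholds comfortably above the
noise floor of a single dataset draw.

## Limitations

* The hyperbolic model's link caps at p = 0.5 (coincident points), an
  inherent property of the distance-based logistic form.
* Mini-batch or stochastic optimization, adaptive per-coordinate steps, and
  second-order Riemannian methods are out of scope; full-batch alternation
  limits practical scale to matrices of a few thousand rows.
* Only isotropic prior covariance is implemented; the loss uses a single
  variance per embedding side.
* The log-map at a general base point generalizes the vertex closed form
  and is exercised mainly through the exp/log round-trip property.
* Cross-fold score pooling assumes the per-fold fits are comparably
  calibrated; strong miscalibration (e.g. unweighted fits on very sparse
  data) degrades pooled rankings even when per-fold rankings are good.
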