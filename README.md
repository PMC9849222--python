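# lorentzmf — hyperbolic logistic matrix factorization for drug–target interactions

Predicting which drugs bind which protein targets is a matrix-completion
problem: given a sparse binary interaction matrix `R` (m drugs × n targets),
rank the unobserved pairs by their probability of interacting.  Classical
logistic matrix factorization embeds drugs and targets in a low-dimensional
*Euclidean* space and scores pairs by a dot product.  But biological
interaction networks are tree-like and heavily clustered, a topology that
flat space represents only with severe metric distortion — while hyperbolic
space, whose circle area grows exponentially with radius, hosts trees almost
isometrically.

`lorentzmf` places both drugs and targets on the hyperboloid (Lorentz)
model of hyperbolic space,

    H^d = { x ∈ R^{d,1} : ⟨x,x⟩_L = −1, x_{d+1} > 0 },
    ⟨x,y⟩_L = x₁y₁ + … + x_d y_d − x_{d+1} y_{d+1},

and models the interaction probability with a logistic link on the squared
Lorentzian distance d_L²(x,y) = −2 − 2⟨x,y⟩_L:

    p_ij = σ( −d_L²(uⁱ, vʲ) ).

The maximum-a-posteriori objective combines a confidence-weighted Bernoulli
likelihood (observed interactions weighted by a constant c > 1), wrapped-
normal priors G(μ₀, σ²I) on the latent rows — the push-forward of a tangent
Gaussian through parallel transport and the exponential map — and an
optional neighborhood regularizer β Σ s_ij d_L²(uⁱ,uʲ) that pulls similar
drugs (targets) together.  Optimization is alternating *Riemannian*
gradient descent: ambient Lorentzian gradients are projected onto tangent
spaces and applied with the exponential map, with per-row gradient clipping
and a three-phase learning-rate annealing.  Interaction-less entities
(new compounds) are embedded by the weighted-profile cold-start through the
closed-form Lorentz centroid.  A minimal Euclidean logistic-MF baseline and
a shared cross-validation/metric harness (CVP pair k-fold, per-drug LOOCV;
AUC/AUPR/PREC@10/AP) make paired geometry comparisons one call.

## Worked example

`examples/03_fit_planted_model.py` generates a 60×50 interaction matrix from
the model's own generative process (wrapped-normal embeddings in H³,
σ² = 1) and fits it:

```
interaction density: 0.032 (96 positives of 3000 cells)
loss: 2207.4 -> 693.3 over 120 epochs (converged=False)
training AUC of fitted model : 0.996
AUC of the planted truth     : 0.938
```

The fitted embedding separates the observed interactions essentially
perfectly; 0.938 is the Bayes-level reference of the planted probabilities
on this dataset.  `examples/04_cross_validation.py` runs the paired
five-fold CVP protocol (every cell held out once per round) on the same
data:

```
method                AUC          AUPR       PREC@10            AP
hyperbolic  0.837 ± 0.007  0.133 ± 0.007  0.250 ± 0.050  0.133 ± 0.007
euclidean   0.681 ± 0.035  0.078 ± 0.012  0.100 ± 0.000  0.078 ± 0.012
```

Both methods were scored on identical held-out folds, so the gap is
attributable to the latent geometry.  The remaining examples cover the
geometry primitives, the wrapped normal, cold-start imputation, and the
tree-data experiment where the hyperbolic factorization beats the Euclidean
one at the same small rank (`examples/06_tree_dimension_advantage.py`).

## Command line

A thin CLI wraps the library for shell use:

```sh
lorentzmf synth data/ --m 60 --n 50 --d-true 3 --seed 0
lorentzmf fit data/interactions.tsv model/ --d 3 --seed 0
lorentzmf predict model/ scores.tsv
lorentzmf cv data/interactions.tsv --k 5 --rounds 10 --d 3
lorentzmf benchmark config.yaml
```

Interaction and similarity matrices use the tab-delimited labeled layout of
the Yamanishi gold-standard sets (first row = target IDs, first column =
drug IDs); `--transpose` reads targets×drugs distributions.

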