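# Methods

This document describes the model implemented in `crowdgp`, the inference
scheme, the synthetic-data generators used for validation, and the numerical
choices that matter for reproducing results.

## Problem setting

We observe features `x_n ∈ R^D` for `N` instances and a sparse set of
annotations `y_{na} ∈ {1..K}` contributed by `A` annotators. Each instance has
an unobserved true class `z_n ∈ {1..K}`; no instance is required to be labeled
by every annotator, and annotators may be unreliable in structured,
class-dependent ways. The goal is to learn a probabilistic classifier
`p(z | x)` together with a per-annotator confusion model, directly from the
noisy crowd labels, without access to ground truth.

## Model

**Annotator noise.** Each annotator `a` has a column-stochastic `K × K`
reliability (confusion) matrix `R^a`, where `R^a_{ij} = p(annotator reports i |
true class j)`. Columns carry independent Dirichlet priors with concentration
`α` (default `α = 1`, i.e. uniform over the simplex; an identity-dominant
prior is available via `perfect_annotator_prior`). Given the true label,
annotations are conditionally independent across annotators:

```
p(y_{na} = i | z_n = j, R^a) = R^a_{ij}
```

**Classifier.** The true-label distribution is a softmax link over `K` latent
functions with independent GP priors:

```
f_k ~ GP(0, κ_θ),   p(z_n = k | f(x_n)) = softmax(f(x_n))_k
```

`κ_θ` is a squared-exponential kernel with shared variance and lengthscale.

**Sparse approximation.** Each latent function is summarized by `M` inducing
points `Z` (chosen by k-means on the inputs and held fixed), with variational
posterior `q(u_k) = N(m_k, L_k L_kᵀ)`. Marginals at arbitrary inputs follow
the standard projection

```
μ(x) = κ(x,Z) K_ZZ⁻¹ m,   σ²(x) = κ(x,x) − a(x)ᵀ(K_ZZ − S) a(x),  a(x) = K_ZZ⁻¹ κ(Z,x)
```

## Inference

We use mean-field variational inference with factorization
`q(Z) q(R) q(U)` and maximize the evidence lower bound

```
ELBO = E_q[Σ log R^a_{y z}] + Σ_n Σ_k q(z_n=k) E_q[log softmax(f_n)_k]
       + H[q(Z)] − KL[q(U) ‖ p(U)] − KL[q(R) ‖ p(R)]
```

- `q(R)`: Dirichlet per annotator column; the update adds expected label
  counts to the prior, so the total added mass per annotator equals exactly
  that annotator's number of annotations (an invariant the tests assert).
- `q(Z)`: categorical per instance; closed-form update combines the
  digamma-expected log-reliabilities of the received votes with a Monte Carlo
  estimate of `E[log softmax]` (Gaussian marginals, `S = 20` draws by default).
- `q(U)` and kernel hyperparameters: stochastic gradient ascent with Adam.
  Gradients with respect to `(m, L)` are analytic; the two kernel
  hyperparameters use central finite differences (`h = 1e-4`), which is exact
  enough at this dimensionality and avoids an autodiff dependency. The
  Cholesky factor is parameterized with an exponential diagonal so positive
  definiteness is unconstrained.

The expected-log-softmax term and its gradients reuse a fixed tensor of
standard-normal draws within each optimization step (common random numbers),
and the reported ELBO trace is evaluated with a single fixed draw tensor so
that the closed-form `q(Z)`/`q(R)` updates are exactly non-decreasing under
the traced objective.

### Warm start

The variational means are initialized by a conjugate GP regression of scaled
vote-share indicators with unit observation noise:

```
m = K_ZZ (K_ZZ + K_ZN K_NZ)⁻¹ K_ZN t,   t = 4 (vote_share − 1/K)
```

Because this is a posterior mean under the GP prior itself, the inducing-point
KL is bounded at initialization regardless of the conditioning of `K_ZZ`; a
plain ridge regression in the projected space can place `m` far outside the
prior and stall optimization.

### Degenerate-solution guard

The coordinate-ascent updates admit a symmetric stationary point — uniform
`q(Z)`, reliability posteriors driven only by uniform responsibilities, and a
flat GP — which vote-seeded ascent can never reach but which may have the
higher bound when the annotations carry no signal. After optimization we
construct that reference configuration explicitly, evaluate both candidates
under the ELBO with shared Monte Carlo draws, and return the winner. This is a
two-candidate multi-start, not a heuristic: the selection criterion is the
training objective itself. On informative data the trained model wins by a
wide margin; on pure-noise data the guard correctly returns the uninformative
solution (near-uniform predictions, near-uniform reliability means).

## Defaults

| Parameter | Default | Rationale |
|---|---|---|
| `M` (inducing points) | 100 | enough for the smooth 2-D test surfaces; reduced automatically to `N` when `N < M` |
| `mc_samples` | 20 | standard error of the softmax expectation is small relative to per-instance entropy differences |
| `learning_rate` | 1e-2 | Adam on `(m, L)`; hyperparameters use 5× this rate (two scalars, smoother objective) |
| `max_iters` | 300 | outer coordinate-ascent sweeps; traces plateau well before this on all fixtures |
| `gp_steps` | 5 | Adam steps per outer sweep |
| jitter | 1e-6 · σ² | added to `K_ZZ`; escalated ×10 up to three times if Cholesky fails |
| `α` (Dirichlet prior) | 1 | uniform; no assumption of annotator competence |

## Synthetic data

`SimulationSpec`/`simulate_dataset` draw Gaussian class clusters (centroids on
a scaled simplex arrangement with configurable `class_separation`, isotropic
`noise_sd`), true labels uniformly, annotator assignments uniformly at random
with a fixed number of labels per instance, and annotations by sampling from
the column of `R^a` selected by the true label. Four named fixtures
(`make_fixture`) cover a separable single-perfect-annotator task, a
three-annotator noisy task, a twenty-annotator study with per-annotator
accuracies drawn from U(0.7, 0.95), and a null task with zero class
separation and uniform-random annotators.

The generators are validated against independent oracles: nearest-centroid
accuracy at high separation, empirical confusion frequencies against the
specified `R` (tolerances set a priori by a 3σ binomial envelope), and
recovery of `R` by the `q(R)` update when true labels are supplied.

## Patch utilities

For segmentation-style data, `LabelMask` grids (0 = unlabeled) are converted
to patch classification sets by a majority rule: a patch is kept only when one
class strictly exceeds 50 % of its pixels. Multi-annotator masks combine by
per-pixel plurality vote (lowest label wins ties; unlabeled pixels ignored).
Dense prediction tiles an image with overlapping windows — stride
`max(1, round(size · (1 − overlap)))`, e.g. 95 % overlap of 32-px windows
gives stride 2 — classifies each window, and assigns each pixel the
highest-probability class averaged over covering windows. Overlap quality is
scored by per-class DICE, with the convention that two empty masks score 1.

## Limitations

- Inducing locations are fixed at their k-means initialization; they are not
  optimized. For low-dimensional inputs this costs little accuracy and keeps
  the gradient code small.
- Kernel hyperparameter gradients are finite-difference; with many more
  hyperparameters (e.g. ARD lengthscales) an analytic or autodiff path would
  be preferable.
- Minibatching is supported for the GP step, but the closed-form `q(Z)`/`q(R)`
  updates sweep the full annotation set each iteration; scaling far beyond
  ~10⁵ annotations would want stochastic versions of those updates too.
- The annotator model assumes conditional independence given the true label
  and a time-invariant confusion matrix per annotator.
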