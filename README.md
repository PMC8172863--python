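# crowdgp

Scalable variational Gaussian-process classification from crowdsourced
labels.

Many labeling efforts — medical image annotation in particular — collect
labels from several annotators of unknown and uneven reliability instead of a
single expert. Majority voting throws away information about *who* labeled
each instance and how each annotator tends to err. `crowdgp` implements a
probabilistic model that learns, jointly and without any ground truth:

- a multiclass classifier `p(z | x)` built from sparse Gaussian-process
  latent functions with a softmax link, and
- a `K × K` column-stochastic confusion matrix per annotator,
  `R^a_{ij} = p(annotator a reports i | true class j)`, with Dirichlet
  priors on the columns.

Inference is mean-field variational: closed-form coordinate updates for the
true-label posterior `q(Z)` and the confusion posteriors `q(R)`, and
stochastic gradient ascent (Adam, analytic gradients, NumPy only) for the
inducing-point posterior `q(U)` and kernel hyperparameters. See
[docs/methods.md](docs/methods.md) for the model, the ELBO, and all numerical
choices.

The package also ships baselines (a plain sparse variational GP on hard
labels; majority voting), synthetic-data generators with known annotator
confusion matrices, segmentation-mask patch utilities (majority-rule patch
extraction, pixelwise plurality vote, overlapping-window dense prediction,
DICE), and an evaluation harness comparing gold / majority-vote /
crowdsourced training regimes.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds one test per acceptance criterion
(confusion-matrix recovery, gold-equivalence, crowd-vs-vote sign test, ELBO
ascent, count conservation, sparse/dense oracle equivalence, deterministic
mechanics, null behavior). The remaining files are unit and oracle tests that
run in a few minutes; the slowest fixtures (full model fits) are shared
session-wide.

## Worked example

```python
import numpy as np
from crowdgp import FitConfig, fit, predict, reliability_mean, make_fixture

# 2000 instances, 3 classes, 20 simulated annotators of varying accuracy,
# ~10 labels per instance, no ground truth shown to the model
ds = make_fixture("twenty-annotator-study", seed=3)

model = fit(ds.X, ds.annotations, FitConfig(seed=0))

# classifier accuracy against the held-back true labels
acc = np.mean(predict(model, ds.X, seed=0).argmax(axis=1) + 1 == ds.true_labels)
print(f"accuracy vs hidden truth: {acc:.3f}")

# recovered confusion matrix for annotator 0 vs the matrix that generated it
err = max(
    np.abs(reliability_mean(model.reliabilities, a) - ds.true_reliabilities[a]).max()
    for a in range(20)
)
print(f"worst annotator confusion error (L-inf): {err:.3f}")
```

Output:

```
accuracy vs hidden truth: 1.000
worst annotator confusion error (L-inf): 0.055
```

The fit takes roughly 1.5 minutes on one CPU core. A command-line interface
covers the same workflow (`crowdgp simulate | fit | predict |
predict-annotator | evaluate | patchify | mvote | dice`); run
`crowdgp --help`.

## Layout

```
src/crowdgp/
  kernels.py     squared-exponential kernel
  gp.py          sparse GP state, projections, inducing-point KL
  crowd.py       annotations, Dirichlet reliability state, softmax link
  model.py       ELBO, closed-form updates, Adam fitting loop, prediction
  simulate.py    synthetic generators and named fixtures
  patches.py     mask patching, plurality vote, dense prediction, DICE
  evaluation.py  metrics, regime comparison, annotator agreement report
  io.py          CSV/JSON/PNG serialization
  cli.py         click command-line interface
```
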