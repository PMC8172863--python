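"""Synthetic crowdsourced datasets with known ground truth.

Features are isotropic Gaussian blobs (one per class) standing in for CNN
patch descriptors: the classifier consumes generic real vectors, and blob
geometry gives analytic accuracy baselines.  Annotations are sampled forward
through the confusion-matrix model: each instance is labeled by a uniformly
random annotator subset, and annotator ``a`` reports a draw from column
``z_n`` of its reliability matrix R^a.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .crowd import AnnotationSet


# ---------------------------------------------------------------------------
# reliability-matrix constructors
# ---------------------------------------------------------------------------


def identity_reliability(n_classes: int) -> np.ndarray:
    """A perfect annotator: reports the true class with probability 1."""
    return np.eye(n_classes)


def uniform_reliability(n_classes: int) -> np.ndarray:
    """An uninformative annotator: labels uniformly regardless of truth."""
    return np.full((n_classes, n_classes), 1.0 / n_classes)


def diagonal_reliability(n_classes: int, accuracy) -> np.ndarray:
    """Symmetric-noise annotator: correct with probability ``accuracy``
    (scalar or per-class vector), errors spread evenly over other classes."""
    acc = np.broadcast_to(np.asarray(accuracy, dtype=float), (n_classes,))
    R = np.empty((n_classes, n_classes))
    for j in range(n_classes):
        R[:, j] = (1.0 - acc[j]) / (n_classes - 1)
        R[j, j] = acc[j]
    return R


def class_swap_reliability(n_classes: int, class_a: int, class_b: int) -> np.ndarray:
    """Adversarial annotator that systematically swaps two classes (1-based)."""
    R = np.eye(n_classes)
    i, j = class_a - 1, class_b - 1
    R[:, [i, j]] = R[:, [j, i]]
    return R


# ---------------------------------------------------------------------------
# simulation spec / dataset bundle
# ---------------------------------------------------------------------------


@dataclass
class SimulationSpec:
    """Study-design parameters for one synthetic dataset.

    ``class_separation`` is the edge length of the regular simplex on which
    the blob centers sit (0 = featureless null); ``noise_sd`` the isotropic
    feature noise; ``labels_per_instance`` the size of the random annotator
    subset drawn per instance.
    """

    n_instances: int
    n_features: int
    n_classes: int
    n_annotators: int
    true_reliabilities: np.ndarray
    labels_per_instance: int
    class_separation: float = 4.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.true_reliabilities = np.asarray(self.true_reliabilities, dtype=float)
        if self.true_reliabilities.shape != (
            self.n_annotators,
            self.n_classes,
            self.n_classes,
        ):
            raise ValueError("true_reliabilities must have shape (A, K, K)")
        sums = self.true_reliabilities.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("reliability columns must each sum to 1")
        if not 1 <= self.labels_per_instance <= self.n_annotators:
            raise ValueError("labels_per_instance must lie in 1..n_annotators")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.class_separation < 0:
            raise ValueError("class_separation must be nonnegative")


@dataclass
class CrowdDataset:
    """Features + annotations + the ground truth that generated them."""

    X: np.ndarray
    annotations: AnnotationSet
    true_labels: np.ndarray
    true_reliabilities: np.ndarray
    spec: SimulationSpec

    @property
    def n_classes(self) -> int:
        return self.spec.n_classes

    def train_test_split(
        self, test_fraction: float = 0.3, seed: int = 0
    ) -> tuple["CrowdDataset", np.ndarray, np.ndarray]:
        """Split into a training bundle and held-out (X_test, y_test).

        Annotations on test instances are dropped; training instance ids are
        renumbered to index the training feature rows.
        """
        n = self.X.shape[0]
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        n_test = int(round(test_fraction * n))
        test_idx = np.sort(perm[:n_test])
        train_idx = np.sort(perm[n_test:])
        remap = {int(old): new for new, old in enumerate(train_idx)}
        Ytr = self.annotations.subset_instances(train_idx)
        Ytr = AnnotationSet(
            np.array([remap[int(i)] for i in Ytr.instance_ids], dtype=int),
            Ytr.annotator_ids,
            Ytr.labels,
            Ytr.n_classes,
            Ytr.n_annotators,
        )
        train = CrowdDataset(
            self.X[train_idx],
            Ytr,
            self.true_labels[train_idx],
            self.true_reliabilities,
            self.spec,
        )
        return train, self.X[test_idx], self.true_labels[test_idx]


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def _simplex_centers(n_classes: int, n_features: int, edge: float) -> np.ndarray:
    """Centers of K blobs at pairwise distance ``edge`` (regular simplex)."""
    K = n_classes
    if K - 1 > n_features:
        raise ValueError(
            f"need n_features >= K-1 to separate {K} classes; got {n_features}"
        )
    centers = np.zeros((K, n_features))
    if edge == 0 or K == 1:
        return centers
    # regular simplex in K-1 dims with unit circumradius, scaled to the edge
    simplex = np.eye(K) - 1.0 / K
    u, s, _ = np.linalg.svd(simplex, full_matrices=False)
    coords = (u[:, : K - 1] * s[: K - 1])  # K x (K-1), pairwise-equidistant
    d = np.linalg.norm(coords[0] - coords[1])
    centers[:, : K - 1] = coords * (edge / d)
    return centers


def simulate_features(spec: SimulationSpec) -> tuple[np.ndarray, np.ndarray]:
    """Draw features and true labels.

    Returns
    -------
    X : (N, D) array
    z : (N,) int array of labels in 1..K, balanced up to rounding.
    """
    rng = np.random.default_rng(spec.seed)
    N, K = spec.n_instances, spec.n_classes
    centers = _simplex_centers(K, spec.n_features, spec.class_separation)
    labels = np.tile(np.arange(1, K + 1), N // K + 1)[:N]
    rng.shuffle(labels)
    X = centers[labels - 1] + spec.noise_sd * rng.standard_normal(
        (N, spec.n_features)
    )
    return X, labels


def simulate_annotations(true_labels: np.ndarray, spec: SimulationSpec) -> AnnotationSet:
    """Sample crowd annotations forward through the confusion-matrix model."""
    # derived stream so features and annotations are independently reproducible
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(2)[1])
    true_labels = np.asarray(true_labels, dtype=int)
    N, A, K = true_labels.size, spec.n_annotators, spec.n_classes
    R = spec.true_reliabilities
    inst, annot, lab = [], [], []
    for n in range(N):
        who = rng.choice(A, size=spec.labels_per_instance, replace=False)
        col = true_labels[n] - 1
        for a in who:
            y = rng.choice(K, p=R[a, :, col]) + 1
            inst.append(n)
            annot.append(int(a))
            lab.append(int(y))
    return AnnotationSet(
        np.array(inst), np.array(annot), np.array(lab), K, A
    )


def simulate_dataset(spec: SimulationSpec) -> CrowdDataset:
    """Features + annotations + ground-truth bundle from one spec."""
    X, z = simulate_features(spec)
    Y = simulate_annotations(z, spec)
    return CrowdDataset(X, Y, z, spec.true_reliabilities.copy(), spec)


# ---------------------------------------------------------------------------
# fixture registry
# ---------------------------------------------------------------------------


def _spec_separable_perfect(seed: int) -> SimulationSpec:
    return SimulationSpec(
        n_instances=200,
        n_features=2,
        n_classes=2,
        n_annotators=1,
        true_reliabilities=identity_reliability(2)[None],
        labels_per_instance=1,
        class_separation=6.0,
        noise_sd=1.0,
        seed=seed,
    )


def _spec_three_noisy(seed: int) -> SimulationSpec:
    R = np.stack(
        [
            diagonal_reliability(3, 0.9),
            diagonal_reliability(3, [0.7, 0.8, 0.6]),
            np.array(  # asymmetric: over-calls class 1
                [
                    [0.8, 0.3, 0.2],
                    [0.1, 0.6, 0.1],
                    [0.1, 0.1, 0.7],
                ]
            ),
        ]
    )
    return SimulationSpec(
        n_instances=2000,
        n_features=2,
        n_classes=3,
        n_annotators=3,
        true_reliabilities=R,
        labels_per_instance=2,
        class_separation=4.0,
        noise_sd=1.0,
        seed=seed,
    )


def _spec_twenty_annotators(seed: int) -> SimulationSpec:
    # 20 novices of varied ability, sparse assignment, 3 tissue-like classes
    rng = np.random.default_rng(seed + 977)
    acc = rng.uniform(0.7, 0.95, size=(20, 3))
    R = np.stack([diagonal_reliability(3, acc[a]) for a in range(20)])
    return SimulationSpec(
        n_instances=2000,
        n_features=2,
        n_classes=3,
        n_annotators=20,
        true_reliabilities=R,
        labels_per_instance=10,
        class_separation=4.0,
        noise_sd=1.0,
        seed=seed,
    )


def _spec_null_random(seed: int) -> SimulationSpec:
    return SimulationSpec(
        n_instances=1500,
        n_features=2,
        n_classes=3,
        n_annotators=3,
        true_reliabilities=np.stack([uniform_reliability(3)] * 3),
        labels_per_instance=2,
        class_separation=0.0,
        noise_sd=1.0,
        seed=seed,
    )


FIXTURES = {
    "separable-perfect": _spec_separable_perfect,
    "three-noisy-annotators": _spec_three_noisy,
    "twenty-annotator-study": _spec_twenty_annotators,
    "null-random": _spec_null_random,
}


def make_fixture(name: str, seed: int = 0) -> CrowdDataset:
    """Return a frozen, seeded dataset from the fixture registry."""
    if name not in FIXTURES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        )
    return simulate_dataset(FIXTURES[name](seed))
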