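"""Crowdsourcing likelihood: annotations, confusion matrices, softmax link.

Each annotator ``a`` is described by a K x K column-stochastic reliability
(confusion) matrix R^a: entry (i, j) is the probability that the annotator
reports class i when the true class is j, so a perfect annotator has R = I.
Every column of R^a carries an independent Dirichlet prior; the
non-informative default sets every concentration parameter to 1.  Latent true
labels connect the annotation model to the GP scores through a softmax link.

Class labels are integers 1..K in all public interfaces (0 is reserved for
"unlabeled" in mask images); probability arrays index classes 0..K-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln, logsumexp

#: tolerance for column-stochasticity checks
STOCHASTIC_ATOL = 1e-9


# ---------------------------------------------------------------------------
# annotation container
# ---------------------------------------------------------------------------


@dataclass
class AnnotationSet:
    """Long-format crowdsourced annotations.

    One record per (instance, annotator) pair; every instance may be labeled
    by a different subset of annotators.  Labels are integers in 1..K.
    """

    instance_ids: np.ndarray
    annotator_ids: np.ndarray
    labels: np.ndarray
    n_classes: int
    n_annotators: int | None = None

    def __post_init__(self) -> None:
        self.instance_ids = np.asarray(self.instance_ids, dtype=int)
        self.annotator_ids = np.asarray(self.annotator_ids, dtype=int)
        self.labels = np.asarray(self.labels, dtype=int)
        if not (
            self.instance_ids.shape == self.annotator_ids.shape == self.labels.shape
        ):
            raise ValueError("instance_ids, annotator_ids and labels must align")
        if self.labels.size and (
            self.labels.min() < 1 or self.labels.max() > self.n_classes
        ):
            raise ValueError(
                f"labels must lie in 1..{self.n_classes}; "
                f"found range [{self.labels.min()}, {self.labels.max()}]"
            )
        pairs = set(zip(self.instance_ids.tolist(), self.annotator_ids.tolist()))
        if len(pairs) != self.instance_ids.size:
            raise ValueError("duplicate (instance, annotator) pair in annotations")
        observed_a = int(self.annotator_ids.max()) + 1 if self.labels.size else 0
        if self.n_annotators is None:
            self.n_annotators = observed_a
        elif self.n_annotators < observed_a:
            raise ValueError(
                f"n_annotators={self.n_annotators} smaller than max annotator id "
                f"{observed_a - 1}"
            )

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[int, int, int]],
        n_classes: int | None = None,
        n_annotators: int | None = None,
    ) -> "AnnotationSet":
        rec = np.asarray(list(records), dtype=int).reshape(-1, 3)
        if n_classes is None:
            n_classes = int(rec[:, 2].max()) if rec.size else 0
        return cls(rec[:, 0], rec[:, 1], rec[:, 2], n_classes, n_annotators)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        n_classes: int | None = None,
        n_annotators: int | None = None,
    ) -> "AnnotationSet":
        """Build from a table with columns instance_id, annotator_id, label."""
        return cls(
            df["instance_id"].to_numpy(int),
            df["annotator_id"].to_numpy(int),
            df["label"].to_numpy(int),
            n_classes if n_classes is not None else int(df["label"].max()),
            n_annotators,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "instance_id": self.instance_ids,
                "annotator_id": self.annotator_ids,
                "label": self.labels,
            }
        )

    def __len__(self) -> int:
        return int(self.instance_ids.size)

    @property
    def label_index(self) -> np.ndarray:
        """0-based class indices of the labels."""
        return self.labels - 1

    @property
    def annotated_instances(self) -> np.ndarray:
        """Sorted unique instance ids that received at least one annotation."""
        return np.unique(self.instance_ids)

    def counts_per_annotator(self) -> np.ndarray:
        """Number of annotations made by each annotator (length n_annotators)."""
        return np.bincount(self.annotator_ids, minlength=self.n_annotators)

    def subset_instances(self, instance_ids: Sequence[int]) -> "AnnotationSet":
        keep = np.isin(self.instance_ids, np.asarray(instance_ids, dtype=int))
        return AnnotationSet(
            self.instance_ids[keep],
            self.annotator_ids[keep],
            self.labels[keep],
            self.n_classes,
            self.n_annotators,
        )


# ---------------------------------------------------------------------------
# reliability (confusion) matrices
# ---------------------------------------------------------------------------


@dataclass
class ReliabilityState:
    """Dirichlet prior and variational posterior over annotator reliabilities.

    ``prior_alpha`` and ``posterior_alpha`` are A x K x K arrays of positive
    concentration parameters; slice ``[a, :, j]`` parameterizes the Dirichlet
    over the j-th *column* of annotator a's confusion matrix.
    """

    prior_alpha: np.ndarray
    posterior_alpha: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.prior_alpha = np.asarray(self.prior_alpha, dtype=float)
        if self.prior_alpha.ndim != 3 or (
            self.prior_alpha.shape[1] != self.prior_alpha.shape[2]
        ):
            raise ValueError("prior_alpha must have shape (A, K, K)")
        if not np.all(self.prior_alpha > 0):
            raise ValueError("Dirichlet parameters must be strictly positive")
        if self.posterior_alpha is None:
            self.posterior_alpha = self.prior_alpha.copy()
        else:
            self.posterior_alpha = np.asarray(self.posterior_alpha, dtype=float)
            if self.posterior_alpha.shape != self.prior_alpha.shape:
                raise ValueError("posterior_alpha shape must match prior_alpha")
            if not np.all(self.posterior_alpha > 0):
                raise ValueError("Dirichlet parameters must be strictly positive")

    @property
    def n_annotators(self) -> int:
        return self.prior_alpha.shape[0]

    @property
    def n_classes(self) -> int:
        return self.prior_alpha.shape[1]

    @classmethod
    def uniform_prior(cls, n_annotators: int, n_classes: int, alpha: float = 1.0):
        """Non-informative prior with every concentration equal to ``alpha``."""
        return cls(np.full((n_annotators, n_classes, n_classes), float(alpha)))

    def _check_annotator(self, annotator: int) -> int:
        a = int(annotator)
        if not 0 <= a < self.n_annotators:
            raise KeyError(
                f"unknown annotator id {annotator}; "
                f"valid ids are 0..{self.n_annotators - 1}"
            )
        return a


def _check_column_stochastic(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    sums = R.sum(axis=0)
    bad = np.flatnonzero(np.abs(sums - 1.0) > STOCHASTIC_ATOL)
    if bad.size:
        raise ValueError(
            f"reliability matrix is not column-stochastic: column {bad[0]} "
            f"sums to {sums[bad[0]]:.12g}"
        )
    return R


def annotation_likelihood(y: np.ndarray, z: np.ndarray, R: np.ndarray) -> float:
    """p(y | z, R) = y^T R z for one-hot y, z and column-stochastic R."""
    R = _check_column_stochastic(R)
    y = np.asarray(y, dtype=float).ravel()
    z = np.asarray(z, dtype=float).ravel()
    for name, v in (("y", y), ("z", z)):
        if v.shape[0] != R.shape[0] or not (
            np.all((v == 0) | (v == 1)) and v.sum() == 1
        ):
            raise ValueError(f"{name} must be a one-hot vector of length {R.shape[0]}")
    return float(y @ R @ z)


def softmax_link(f: np.ndarray) -> np.ndarray:
    """Softmax over the last axis, computed with max-subtraction.

    Maps real-valued latent scores to a probability vector; adding a constant
    to every component leaves the output unchanged.
    """
    f = np.asarray(f, dtype=float)
    if np.any(np.isnan(f)):
        raise ValueError("softmax_link received NaN input")
    shifted = f - np.max(f, axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / np.sum(e, axis=-1, keepdims=True)


def expected_log_reliability(state: ReliabilityState, annotator: int) -> np.ndarray:
    """E_q[log R^a] under the Dirichlet posterior, column-wise.

    Entry (i, j) is psi(alpha_ij) - psi(sum_i alpha_ij) with psi the digamma
    function; all entries are <= 0.
    """
    a = state._check_annotator(annotator)
    alpha = state.posterior_alpha[a]
    return digamma(alpha) - digamma(alpha.sum(axis=0, keepdims=True))


def reliability_mean(state: ReliabilityState, annotator: int) -> np.ndarray:
    """Posterior-mean confusion matrix (column-stochastic) of one annotator."""
    a = state._check_annotator(annotator)
    alpha = state.posterior_alpha[a]
    return alpha / alpha.sum(axis=0, keepdims=True)


def dirichlet_kl(posterior_alpha: np.ndarray, prior_alpha: np.ndarray) -> float:
    """Sum of KL[Dir(post) || Dir(prior)] over all trailing columns.

    Accepts arrays of shape (..., K, K) or (K,) column vectors; the Dirichlet
    lives along axis -2 (the rows of each column).
    """
    q = np.asarray(posterior_alpha, dtype=float)
    p = np.asarray(prior_alpha, dtype=float)
    if q.shape != p.shape:
        raise ValueError("posterior and prior alpha shapes must match")
    if q.ndim == 1:
        q = q[:, None]
        p = p[:, None]
    q0 = q.sum(axis=-2, keepdims=True)
    p0 = p.sum(axis=-2, keepdims=True)
    term = (
        gammaln(q0).sum()
        - gammaln(q).sum()
        - gammaln(p0).sum()
        + gammaln(p).sum()
        + np.sum((q - p) * (digamma(q) - digamma(q0)))
    )
    return float(max(term, 0.0))


# ---------------------------------------------------------------------------
# true-label posterior
# ---------------------------------------------------------------------------


@dataclass
class TrueLabelPosterior:
    """Categorical variational posterior q(z_n) over the latent true labels.

    ``probs`` is N x K with rows summing to 1; ``instance_ids`` maps rows to
    instances (row n of a feature matrix has instance id n).
    """

    probs: np.ndarray
    instance_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2:
            raise ValueError("probs must be 2-D (N x K)")
        if np.any(self.probs < 0):
            raise ValueError("probs must be nonnegative")
        row_sums = self.probs.sum(axis=1)
        if not np.allclose(row_sums, 1.0, atol=1e-9):
            raise ValueError("each row of probs must sum to 1 within 1e-9")
        if self.instance_ids is None:
            self.instance_ids = np.arange(self.probs.shape[0])
        else:
            self.instance_ids = np.asarray(self.instance_ids, dtype=int)
            if self.instance_ids.shape[0] != self.probs.shape[0]:
                raise ValueError("instance_ids must align with probs rows")

    @property
    def n_classes(self) -> int:
        return self.probs.shape[1]

    def map_labels(self) -> np.ndarray:
        """Most probable class per row, as labels in 1..K (ties -> smallest)."""
        return np.argmax(self.probs, axis=1) + 1

    def entropy(self) -> float:
        """Total Shannon entropy of the posterior, in nats."""
        p = self.probs
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * np.log(p), 0.0)
        return float(-terms.sum())


def normalize_log_probs(log_probs: np.ndarray) -> np.ndarray:
    """Row-normalize unnormalized log-probabilities into a categorical table."""
    log_z = logsumexp(log_probs, axis=1, keepdims=True)
    p = np.exp(log_probs - log_z)
    return p / p.sum(axis=1, keepdims=True)
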