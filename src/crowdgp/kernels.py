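"""Squared-exponential covariance function.

The classifier places independent zero-mean GP priors on the K latent score
functions, all sharing one squared-exponential (SE) kernel

    k(x, x') = sigma^2 * exp(-||x - x'||^2 / (2 * l^2))

with variance ``sigma^2`` and a single lengthscale ``l`` common to all feature
dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class KernelParams:
    """Hyperparameters of the SE kernel.

    Parameters
    ----------
    variance
        Prior marginal variance sigma^2 of every latent function. Must be > 0.
    lengthscale
        Isotropic lengthscale l, in feature-space distance units. Must be > 0.
    """

    variance: float = 1.0
    lengthscale: float = 1.0

    def __post_init__(self) -> None:
        if not (self.variance > 0):
            raise ValueError(f"kernel variance must be > 0, got {self.variance}")
        if not (self.lengthscale > 0):
            raise ValueError(f"kernel lengthscale must be > 0, got {self.lengthscale}")


def _sq_dists(X1: np.ndarray, X2: np.ndarray) -> np.ndarray:
    """Pairwise squared Euclidean distances, clipped at zero."""
    n1 = np.sum(X1 * X1, axis=1)[:, None]
    n2 = np.sum(X2 * X2, axis=1)[None, :]
    d2 = n1 + n2 - 2.0 * (X1 @ X2.T)
    return np.maximum(d2, 0.0)


def se_kernel(x_i: np.ndarray, x_j: np.ndarray, params: KernelParams) -> float:
    """Evaluate the SE kernel between two feature vectors.

    Raises
    ------
    ValueError
        If the two vectors have different dimension.
    """
    x_i = np.asarray(x_i, dtype=float).ravel()
    x_j = np.asarray(x_j, dtype=float).ravel()
    if x_i.shape[0] != x_j.shape[0]:
        raise ValueError(
            f"dimension mismatch: x_i has dimension {x_i.shape[0]}, "
            f"x_j has dimension {x_j.shape[0]}"
        )
    d2 = float(np.sum((x_i - x_j) ** 2))
    return float(params.variance * np.exp(-d2 / (2.0 * params.lengthscale**2)))


def kernel_matrix(X1: np.ndarray, X2: np.ndarray, params: KernelParams) -> np.ndarray:
    """SE Gram matrix between the rows of ``X1`` (A x D) and ``X2`` (B x D).

    When ``X1 is X2`` (or equal), the result is symmetric positive
    semidefinite up to floating-point roundoff.
    """
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    if X1.shape[1] != X2.shape[1]:
        raise ValueError(
            f"dimension mismatch: X1 has {X1.shape[1]} columns, "
            f"X2 has {X2.shape[1]} columns"
        )
    d2 = _sq_dists(X1, X2)
    return params.variance * np.exp(-d2 / (2.0 * params.lengthscale**2))
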