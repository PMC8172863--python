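"""Sparse variational GP state and predictive marginals.

The posterior over the K latent functions is approximated through M inducing
points: a variational Gaussian q(u_k) = N(m_k, S_k) is kept per latent
function at shared inducing locations, and the predictive marginals at new
inputs follow from composing the exact sparse conditional p(f | u) with q(u):

    mean_k(x) = a(x)^T m_k
    var_k(x)  = k(x, x) - a(x)^T K_mm a(x) + a(x)^T S_k a(x)

with a(x) = K_mm^{-1} k_m(x).  Covariances are kept as lower-triangular
Cholesky factors so S_k is positive definite by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_solve, cholesky, solve_triangular

from .kernels import KernelParams, kernel_matrix

#: relative jitter added to the diagonal of K_mm before factorization
JITTER = 1e-6

#: floor for predictive marginal variances
VAR_FLOOR = 1e-12


@dataclass
class SparseGPState:
    """Variational state of the sparse multiclass GP.

    Attributes
    ----------
    inducing_locations
        M x D inducing inputs.
    q_mean
        M x K variational means, one column per latent function.
    q_chol
        K x M x M lower-triangular Cholesky factors of the variational
        covariances; strictly positive diagonals.
    kernel
        Shared SE kernel hyperparameters.
    """

    inducing_locations: np.ndarray
    q_mean: np.ndarray
    q_chol: np.ndarray
    kernel: KernelParams = field(default_factory=KernelParams)

    def __post_init__(self) -> None:
        self.inducing_locations = np.atleast_2d(
            np.asarray(self.inducing_locations, dtype=float)
        )
        self.q_mean = np.asarray(self.q_mean, dtype=float)
        self.q_chol = np.asarray(self.q_chol, dtype=float)
        M = self.inducing_locations.shape[0]
        if M < 1:
            raise ValueError("at least one inducing point is required")
        if self.q_mean.shape[0] != M:
            raise ValueError("q_mean rows must match the number of inducing points")
        if self.q_chol.shape != (self.q_mean.shape[1], M, M):
            raise ValueError("q_chol must have shape (K, M, M)")
        diags = np.diagonal(self.q_chol, axis1=1, axis2=2)
        if not np.all(diags > 0):
            raise ValueError("q_chol factors must have strictly positive diagonals")

    @property
    def num_inducing(self) -> int:
        return self.inducing_locations.shape[0]

    @property
    def num_latent(self) -> int:
        return self.q_mean.shape[1]

    @classmethod
    def prior(
        cls, inducing_locations: np.ndarray, n_latent: int, kernel: KernelParams
    ) -> "SparseGPState":
        """State with q(U) equal to the GP prior at the inducing locations."""
        Z = np.atleast_2d(np.asarray(inducing_locations, dtype=float))
        M = Z.shape[0]
        Kmm = kernel_matrix(Z, Z, kernel) + JITTER * kernel.variance * np.eye(M)
        Lm = cholesky(Kmm, lower=True)
        return cls(
            inducing_locations=Z,
            q_mean=np.zeros((M, n_latent)),
            q_chol=np.repeat(Lm[None, :, :], n_latent, axis=0),
            kernel=kernel,
        )


def _chol_kmm(Z: np.ndarray, kernel: KernelParams) -> np.ndarray:
    """Lower Cholesky factor of the jittered inducing Gram matrix."""
    M = Z.shape[0]
    Kmm = kernel_matrix(Z, Z, kernel) + JITTER * kernel.variance * np.eye(M)
    try:
        return cholesky(Kmm, lower=True)
    except np.linalg.LinAlgError:  # pragma: no cover - heavy degeneracy
        # escalate jitter rather than returning NaNs
        Kmm = Kmm + 1e-4 * kernel.variance * np.eye(M)
        return cholesky(Kmm, lower=True)


def _projection(
    state: SparseGPState, X_new: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (Lm, A, base_var) for inputs ``X_new``.

    ``A`` is the P x M matrix K_pm K_mm^{-1}; ``base_var`` is the P-vector
    k(x,x) - diag(A K_mp), the predictive variance with q(U) collapsed to a
    point mass.
    """
    Z = state.inducing_locations
    if X_new.shape[1] != Z.shape[1]:
        raise ValueError(
            f"dimension mismatch: inputs have {X_new.shape[1]} features, "
            f"inducing locations have {Z.shape[1]}"
        )
    Lm = _chol_kmm(Z, state.kernel)
    Kpm = kernel_matrix(X_new, Z, state.kernel)
    # W = Lm^{-1} K_mp, so diag(A K_mp) = column sums of W^2
    W = solve_triangular(Lm, Kpm.T, lower=True)
    A = cho_solve((Lm, True), Kpm.T).T
    base_var = state.kernel.variance - np.sum(W * W, axis=0)
    return Lm, A, base_var


def latent_marginals(
    state: SparseGPState, X_new: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian marginals of q(f) at ``X_new`` for every latent function.

    Returns
    -------
    mean, var
        P x K arrays; ``var`` is strictly positive (floored at 1e-12).
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    _, A, base_var = _projection(state, X_new)
    mean = A @ state.q_mean
    K = state.num_latent
    var = np.empty((X_new.shape[0], K))
    for k in range(K):
        AL = A @ state.q_chol[k]
        var[:, k] = base_var + np.sum(AL * AL, axis=1)
    var = np.maximum(var, VAR_FLOOR)
    if not (np.all(np.isfinite(mean)) and np.all(np.isfinite(var))):
        raise FloatingPointError("non-finite latent marginals")
    return mean, var


def kl_inducing(state: SparseGPState) -> float:
    """KL[q(U) || p(U)] summed over the K latent functions.

    Both distributions live at the inducing locations; p(u_k) = N(0, K_mm).
    """
    Z = state.inducing_locations
    M = Z.shape[0]
    Lm = _chol_kmm(Z, state.kernel)
    logdet_kmm = 2.0 * np.sum(np.log(np.diag(Lm)))
    total = 0.0
    for k in range(state.num_latent):
        Lk = state.q_chol[k]
        m_k = state.q_mean[:, k]
        tr = np.sum(solve_triangular(Lm, Lk, lower=True) ** 2)
        maha = np.sum(solve_triangular(Lm, m_k, lower=True) ** 2)
        logdet_s = 2.0 * np.sum(np.log(np.diag(Lk)))
        total += 0.5 * (tr + maha - M + logdet_kmm - logdet_s)
    return float(max(total, 0.0))
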