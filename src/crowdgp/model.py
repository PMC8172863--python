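"""Variational training of the crowdsourced GP classifier.

The joint model couples three blocks: per-annotator column-stochastic
confusion matrices with Dirichlet priors, a latent categorical true label per
instance, and K softmax-linked latent functions with sparse GP priors.  The
posterior is approximated by the mean-field family

    q(Z) q(R) q(U) ,

where q(Z) is categorical per instance, q(R) is Dirichlet per confusion
column and q(U) is a full-covariance Gaussian per latent function at the
inducing locations.  Training interleaves

* closed-form coordinate updates of q(R) (Dirichlet counts weighted by q(Z))
  and q(Z) (softmax expectation + expected log-reliability votes), with
* Adam ascent on the variational Gaussian (analytic gradients) and on the two
  kernel hyperparameters (central finite differences), maximizing the ELBO

    E_q[log p(Y|Z,R)] + E_q[log p(Z|F)] + H[q(Z)]
        - KL[q(U)||p(U)] - KL[q(R)||p(R)] .

The intractable E_q[log softmax] is estimated by Monte Carlo from the
Gaussian marginals of q(F); all draws are governed by the fit seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import cho_solve, solve_triangular
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .crowd import (
    AnnotationSet,
    ReliabilityState,
    TrueLabelPosterior,
    dirichlet_kl,
    expected_log_reliability,
    normalize_log_probs,
    reliability_mean,
)
from .gp import JITTER, VAR_FLOOR, SparseGPState, _chol_kmm, latent_marginals
from .kernels import KernelParams, kernel_matrix

log = logging.getLogger(__name__)


@dataclass
class FitConfig:
    """Training configuration.

    Attributes
    ----------
    M
        Number of inducing points (capped at the number of annotated
        instances at fit time).
    mc_samples
        Monte-Carlo draws for every softmax expectation.
    learning_rate
        Adam step size for the GP variational parameters and hyperparameters.
    max_iters
        Outer coordinate-ascent iterations.
    gp_steps
        Adam steps on q(U) per outer iteration.
    batch_size
        Instances per stochastic minibatch; ``None`` = full batch.
    seed
        Master seed; every random draw (k-means init, MC sampling,
        minibatching) derives from it.
    tol, tol_window
        Stop early when the relative ELBO change over ``tol_window``
        iterations falls below ``tol``.
    learn_hyperparams
        Whether to optimize the kernel variance and lengthscale.
    """

    M: int = 100
    mc_samples: int = 20
    learning_rate: float = 1e-2
    max_iters: int = 300
    gp_steps: int = 5
    batch_size: int | None = None
    seed: int = 0
    tol: float = 1e-6
    tol_window: int = 50
    learn_hyperparams: bool = True

    def __post_init__(self) -> None:
        if self.M < 1 or self.mc_samples < 1 or self.max_iters < 1:
            raise ValueError("M, mc_samples and max_iters must be positive")
        if self.learning_rate <= 0 or self.tol <= 0:
            raise ValueError("learning_rate and tol must be positive")


@dataclass
class SVGPCRModel:
    """Fitted crowdsourced GP classifier."""

    gp: SparseGPState
    reliabilities: ReliabilityState
    q_z: TrueLabelPosterior
    trace: np.ndarray
    config: FitConfig
    n_classes: int
    n_annotators: int


# ---------------------------------------------------------------------------
# closed-form coordinate updates
# ---------------------------------------------------------------------------


def update_q_R(
    q_z: TrueLabelPosterior, Y: AnnotationSet, prior: ReliabilityState
) -> ReliabilityState:
    """Closed-form Dirichlet update of the reliability posteriors.

    alpha_hat[a, i, j] = alpha[a, i, j] + sum over annotations (n, a) with
    label i of q(z_n = j).  The total mass added for annotator ``a`` equals
    its annotation count exactly.
    """
    row_of = {int(i): r for r, i in enumerate(q_z.instance_ids)}
    try:
        rows = np.fromiter(
            (row_of[int(i)] for i in Y.instance_ids), dtype=int, count=len(Y)
        )
    except KeyError as exc:
        raise ValueError(
            f"annotation references instance {exc.args[0]} absent from q(Z)"
        ) from None
    post = prior.prior_alpha.copy()
    if len(Y):
        np.add.at(post, (Y.annotator_ids, Y.label_index), q_z.probs[rows])
    return ReliabilityState(prior.prior_alpha, post)


def _mc_expected_log_softmax(
    mean: np.ndarray, var: np.ndarray, eps: np.ndarray
) -> np.ndarray:
    """MC estimate of E[log softmax_k(f)] per point and class (N x K)."""
    f = mean[None, :, :] + np.sqrt(var)[None, :, :] * eps
    logp = f - logsumexp(f, axis=-1, keepdims=True)
    return logp.mean(axis=0)


def _annotation_log_votes(
    Y: AnnotationSet, rel: ReliabilityState, rows: np.ndarray, n_rows: int
) -> np.ndarray:
    """Sum of expected log-reliabilities per (instance row, true class)."""
    K = rel.n_classes
    elogr = np.stack(
        [expected_log_reliability(rel, a) for a in range(rel.n_annotators)]
    )
    votes = np.zeros((n_rows, K))
    if len(Y):
        np.add.at(votes, rows, elogr[Y.annotator_ids, Y.label_index, :])
    return votes


def update_q_Z(
    q_f: tuple[np.ndarray, np.ndarray],
    Y: AnnotationSet,
    rel: ReliabilityState,
    mc_samples: int = 20,
    seed: int = 0,
    instance_ids: np.ndarray | None = None,
    eps: np.ndarray | None = None,
) -> TrueLabelPosterior:
    """Closed-form categorical update of the true-label posterior.

    ``q_f`` holds the Gaussian marginals (mean, var), each N x K, for the
    instances listed in ``instance_ids`` (defaults to rows 0..N-1).  The
    softmax expectation is Monte-Carlo estimated with ``mc_samples`` draws
    under ``seed``; pass ``eps`` (S x N x K standard normals) to pin the
    draws explicitly.
    """
    mean, var = (np.asarray(m, dtype=float) for m in q_f)
    n, K = mean.shape
    if instance_ids is None:
        instance_ids = np.arange(n)
    if eps is None:
        rng = np.random.default_rng(seed)
        eps = rng.standard_normal((mc_samples, n, K))
    els = _mc_expected_log_softmax(mean, var, eps)
    row_of = {int(i): r for r, i in enumerate(instance_ids)}
    rows = np.fromiter((row_of[int(i)] for i in Y.instance_ids), dtype=int, count=len(Y))
    votes = _annotation_log_votes(Y, rel, rows, n)
    return TrueLabelPosterior(normalize_log_probs(els + votes), instance_ids)


# ---------------------------------------------------------------------------
# ELBO
# ---------------------------------------------------------------------------


def _check_finite(name: str, value: float) -> float:
    if not np.isfinite(value):
        raise FloatingPointError(f"ELBO term '{name}' is not finite: {value}")
    return float(value)


def elbo(
    model: SVGPCRModel,
    X: np.ndarray,
    Y: AnnotationSet,
    mc_samples: int = 20,
    seed: int = 0,
    eps: np.ndarray | None = None,
) -> float:
    """Evidence lower bound of the mean-field posterior at the current state.

    Assembled as annotation term + softmax term + q(Z) entropy
    - KL[q(U)||p(U)] - KL[q(R)||p(R)]; every KL is nonnegative.
    """
    from .gp import kl_inducing

    X = np.atleast_2d(np.asarray(X, dtype=float))
    ids = model.q_z.instance_ids
    mean, var = latent_marginals(model.gp, X[ids])
    if eps is None:
        rng = np.random.default_rng(seed)
        eps = rng.standard_normal((mc_samples, mean.shape[0], mean.shape[1]))
    els = _mc_expected_log_softmax(mean, var, eps)
    q = model.q_z.probs
    row_of = {int(i): r for r, i in enumerate(ids)}
    rows = np.fromiter((row_of[int(i)] for i in Y.instance_ids), dtype=int, count=len(Y))
    votes = _annotation_log_votes(Y, model.reliabilities, rows, q.shape[0])
    ann_term = _check_finite("annotation", float(np.sum(q * votes)))
    gp_term = _check_finite("softmax", float(np.sum(q * els)))
    entropy = _check_finite("entropy", model.q_z.entropy())
    kl_u = _check_finite("KL_U", kl_inducing(model.gp))
    kl_r = _check_finite(
        "KL_R",
        dirichlet_kl(
            model.reliabilities.posterior_alpha, model.reliabilities.prior_alpha
        ),
    )
    return ann_term + gp_term + entropy - kl_u - kl_r


# ---------------------------------------------------------------------------
# GP objective and gradients
# ---------------------------------------------------------------------------


class _Adam:
    """Minimal Adam ascent on a flat parameter vector."""

    def __init__(self, n: int, lr: float) -> None:
        self.lr = lr
        self.m = np.zeros(n)
        self.v = np.zeros(n)
        self.t = 0

    def step(self, params: np.ndarray, grad: np.ndarray) -> np.ndarray:
        self.t += 1
        self.m = 0.9 * self.m + 0.1 * grad
        self.v = 0.999 * self.v + 0.001 * grad * grad
        mhat = self.m / (1 - 0.9**self.t)
        vhat = self.v / (1 - 0.999**self.t)
        return params + self.lr * mhat / (np.sqrt(vhat) + 1e-8)


def _chol_from_raw(raw: np.ndarray) -> np.ndarray:
    """Lower-triangular factor with exp-diagonal from an unconstrained array."""
    L = np.tril(raw, -1)
    idx = np.arange(raw.shape[-1])
    L[..., idx, idx] = np.exp(raw[..., idx, idx])
    return L


def _raw_from_chol(L: np.ndarray) -> np.ndarray:
    raw = np.tril(L, -1)
    idx = np.arange(L.shape[-1])
    raw[..., idx, idx] = np.log(L[..., idx, idx])
    return raw


def _projection_arrays(
    Z: np.ndarray, X: np.ndarray, kernel: KernelParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(Lm, A, base_var) for training inputs X under the current kernel."""
    M = Z.shape[0]
    Kmm = kernel_matrix(Z, Z, kernel) + JITTER * kernel.variance * np.eye(M)
    Lm = np.linalg.cholesky(Kmm)
    Knm = kernel_matrix(X, Z, kernel)
    W = solve_triangular(Lm, Knm.T, lower=True)
    A = cho_solve((Lm, True), Knm.T).T
    base_var = np.maximum(kernel.variance - np.sum(W * W, axis=0), 0.0)
    return Lm, A, base_var


def _gp_objective(
    Lm: np.ndarray,
    A: np.ndarray,
    base_var: np.ndarray,
    m: np.ndarray,
    L: np.ndarray,
    q: np.ndarray,
    eps: np.ndarray,
    scale: float = 1.0,
    with_grads: bool = True,
):
    """GP block of the ELBO (softmax data term - KL[q(U)||p(U)]) and its
    gradients with respect to ``m`` and the Cholesky factors ``L``.

    ``q`` are the fixed q(Z) weights for the rows of ``A``; ``eps`` is the
    S x N x K tensor of standard-normal draws; ``scale`` reweights the data
    term under minibatching.
    """
    M, K = m.shape
    mu = A @ m
    var = np.empty_like(mu)
    AL = []
    for k in range(K):
        ALk = A @ L[k]
        AL.append(ALk)
        var[:, k] = base_var + np.sum(ALk * ALk, axis=1)
    clipped = var < VAR_FLOOR
    var = np.maximum(var, VAR_FLOOR)
    sd = np.sqrt(var)
    f = mu[None] + sd[None] * eps
    logp = f - logsumexp(f, axis=-1, keepdims=True)
    data = scale * float(np.sum(q * logp.mean(axis=0)))

    # KL[q(U)||p(U)]
    logdet_kmm = 2.0 * np.sum(np.log(np.diag(Lm)))
    kl = 0.0
    KinvL = np.empty_like(L)
    Kinvm = np.empty_like(m)
    for k in range(K):
        KinvL[k] = cho_solve((Lm, True), L[k])
        Kinvm[:, k] = cho_solve((Lm, True), m[:, k])
        tr = float(np.sum(L[k] * KinvL[k]))
        maha = float(m[:, k] @ Kinvm[:, k])
        logdet_s = 2.0 * np.sum(np.log(np.diag(L[k])))
        kl += 0.5 * (tr + maha - M + logdet_kmm - logdet_s)
    obj = data - kl
    if not with_grads:
        return obj, None, None

    p = np.exp(logp)
    G = q[None] - p  # d/df of sum_j q_j log softmax_j
    g_mu = scale * G.mean(axis=0)
    g_var = scale * (G * eps).mean(axis=0) / (2.0 * sd)
    g_var[clipped] = 0.0
    grad_m = A.T @ g_mu - Kinvm
    grad_L = np.empty_like(L)
    idx = np.arange(M)
    for k in range(K):
        B_L = (A * g_var[:, k : k + 1]).T @ AL[k]  # = A^T diag(g_var) A L_k
        gk = 2.0 * np.tril(B_L) - np.tril(KinvL[k])
        gk[idx, idx] += 1.0 / np.diag(L[k])
        grad_L[k] = gk
    return obj, grad_m, grad_L


def _objective_at_hypers(
    log_variance: float,
    log_lengthscale: float,
    Z: np.ndarray,
    X: np.ndarray,
    m: np.ndarray,
    L: np.ndarray,
    q: np.ndarray,
    eps: np.ndarray,
    scale: float,
) -> float:
    kernel = KernelParams(float(np.exp(log_variance)), float(np.exp(log_lengthscale)))
    Lm, A, base_var = _projection_arrays(Z, X, kernel)
    obj, _, _ = _gp_objective(Lm, A, base_var, m, L, q, eps, scale, with_grads=False)
    return obj


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _init_inducing(X: np.ndarray, M: int, seed: int) -> np.ndarray:
    if M >= X.shape[0]:
        return X.copy()
    km = KMeans(n_clusters=M, n_init=3, random_state=seed).fit(X)
    return km.cluster_centers_


def _init_lengthscale(X: np.ndarray, rng: np.random.Generator) -> float:
    """Median pairwise distance on a subsample; a standard SE initialization."""
    n = X.shape[0]
    sub = X if n <= 500 else X[rng.choice(n, 500, replace=False)]
    d2 = (
        np.sum(sub * sub, axis=1)[:, None]
        + np.sum(sub * sub, axis=1)[None, :]
        - 2 * sub @ sub.T
    )
    med = float(np.median(np.sqrt(np.maximum(d2[np.triu_indices(sub.shape[0], 1)], 0))))
    return max(med, 1e-3)


def perfect_annotator_prior(
    n_classes: int, diagonal: float = 100.0, off_diagonal: float = 0.01
) -> ReliabilityState:
    """Dirichlet prior concentrated on the identity confusion matrix.

    Used to express that a (single) annotator is trusted, which reduces the
    crowd model to a plain GP classifier on that annotator's labels.
    """
    alpha = np.full((1, n_classes, n_classes), off_diagonal)
    alpha[0, np.arange(n_classes), np.arange(n_classes)] = diagonal
    return ReliabilityState(alpha)


def fit(
    X: np.ndarray,
    Y: AnnotationSet,
    config: FitConfig | None = None,
    n_classes: int | None = None,
    reliability_prior: ReliabilityState | None = None,
) -> SVGPCRModel:
    """Train the crowdsourced GP classifier by variational inference.

    Instances without annotations are excluded from training.  Deterministic
    given ``config.seed``.
    """
    config = config or FitConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    K = n_classes if n_classes is not None else Y.n_classes
    A_count = Y.n_annotators
    ids = Y.annotated_instances
    if ids.size == 0:
        raise ValueError("annotation set is empty; nothing to train on")
    if ids.max() >= X.shape[0]:
        raise ValueError(
            f"annotation references instance {ids.max()} but features have "
            f"{X.shape[0]} rows"
        )
    X_train = X[ids]
    n = X_train.shape[0]

    M = config.M
    if M > n:
        log.warning("reducing M from %d to the number of instances %d", M, n)
        M = n

    ss = np.random.SeedSequence(config.seed)
    ss_kmeans, ss_train, ss_eval = ss.spawn(3)
    kmeans_seed = int(ss_kmeans.generate_state(1)[0] % (2**31))
    rng_train = np.random.default_rng(ss_train)
    rng_eval = np.random.default_rng(ss_eval)

    Z = _init_inducing(X_train, M, kmeans_seed)
    kernel = KernelParams(1.0, _init_lengthscale(X_train, rng_train))

    Lm, A_proj, base_var = _projection_arrays(Z, X_train, kernel)
    m = np.zeros((M, K))
    L = np.repeat(Lm[None], K, axis=0)
    raw = _raw_from_chol(L)
    log_hypers = np.array([np.log(kernel.variance), np.log(kernel.lengthscale)])

    if reliability_prior is None:
        reliability_prior = ReliabilityState.uniform_prior(A_count, K)
    if reliability_prior.prior_alpha.shape != (A_count, K, K):
        raise ValueError(
            f"reliability prior shape {reliability_prior.prior_alpha.shape} does "
            f"not match (A={A_count}, K={K})"
        )

    # q(Z) init: smoothed annotation votes
    row_of = {int(i): r for r, i in enumerate(ids)}
    rows = np.fromiter((row_of[int(i)] for i in Y.instance_ids), dtype=int, count=len(Y))
    votes = np.full((n, K), 0.5)
    np.add.at(votes, (rows, Y.label_index), 1.0)
    q_z = TrueLabelPosterior(votes / votes.sum(axis=1, keepdims=True), ids)
    rel = update_q_R(q_z, Y, reliability_prior)

    # warm-start the variational means with a conjugate GP regression of
    # scaled vote indicators (unit observation noise): this is the inducing
    # posterior mean of a Gaussian pseudo-likelihood under the same prior, so
    # the inducing-point KL stays bounded while the means start near the
    # vote-implied decision surface
    targets = 4.0 * (q_z.probs - 1.0 / K)
    Kmn = kernel_matrix(Z, X_train, kernel)
    Kmm = Lm @ Lm.T
    m = Kmm @ np.linalg.solve(Kmm + Kmn @ Kmn.T, Kmn @ targets)

    adam_qu = _Adam(m.size + raw.size, config.learning_rate)
    # the two kernel hyperparameters move on a slow timescale (one step per
    # outer iteration); give them a faster rate so they co-adapt with q(U)
    adam_hyp = _Adam(2, 5.0 * config.learning_rate)
    S = config.mc_samples
    eval_eps = rng_eval.standard_normal((S, n, K))

    batch = config.batch_size
    use_minibatch = batch is not None and batch < n

    trace: list[float] = []
    for it in range(config.max_iters):
        if use_minibatch:
            bidx = rng_train.choice(n, batch, replace=False)
            scale = n / batch
        else:
            bidx = slice(None)
            scale = 1.0
        Yb = Y.subset_instances(ids[bidx]) if use_minibatch else Y

        # --- closed-form updates -------------------------------------
        rel = update_q_R(q_z, Y, reliability_prior)
        mu = A_proj @ m
        var = np.empty_like(mu)
        for k in range(K):
            ALk = A_proj @ L[k]
            var[:, k] = base_var + np.sum(ALk * ALk, axis=1)
        var = np.maximum(var, VAR_FLOOR)
        eps_qz = rng_train.standard_normal((S, mu[bidx].shape[0], K))
        q_new = update_q_Z(
            (mu[bidx], var[bidx]), Yb, rel,
            instance_ids=ids[bidx], eps=eps_qz,
        )
        probs = q_z.probs.copy()
        probs[bidx] = q_new.probs
        q_z = TrueLabelPosterior(probs, ids)

        # --- gradient steps on q(U) ----------------------------------
        Xb = X_train[bidx]
        Ab = A_proj[bidx]
        bvb = base_var[bidx]
        qb = q_z.probs[bidx]
        for _ in range(config.gp_steps):
            eps = rng_train.standard_normal((S, Xb.shape[0], K))
            _, grad_m, grad_L = _gp_objective(Lm, Ab, bvb, m, L, qb, eps, scale)
            # chain through the exp-diagonal parameterization
            grad_raw = grad_L.copy()
            didx = np.arange(M)
            grad_raw[:, didx, didx] *= np.diagonal(L, axis1=1, axis2=2)
            flat = np.concatenate([m.ravel(), raw.ravel()])
            gflat = np.concatenate([grad_m.ravel(), grad_raw.ravel()])
            flat = adam_qu.step(flat, gflat)
            m = flat[: m.size].reshape(M, K)
            raw = flat[m.size :].reshape(K, M, M)
            L = _chol_from_raw(raw)

        # --- hyperparameter step (central finite differences) --------
        if config.learn_hyperparams:
            eps = rng_train.standard_normal((S, Xb.shape[0], K))
            h = 1e-4
            ghyp = np.empty(2)
            for j in range(2):
                lo, hi = log_hypers.copy(), log_hypers.copy()
                lo[j] -= h
                hi[j] += h
                f_hi = _objective_at_hypers(hi[0], hi[1], Z, Xb, m, L, qb, eps, scale)
                f_lo = _objective_at_hypers(lo[0], lo[1], Z, Xb, m, L, qb, eps, scale)
                ghyp[j] = (f_hi - f_lo) / (2 * h)
            log_hypers = adam_hyp.step(log_hypers, ghyp)
            kernel = KernelParams(float(np.exp(log_hypers[0])), float(np.exp(log_hypers[1])))
            Lm, A_proj, base_var = _projection_arrays(Z, X_train, kernel)

        # --- ELBO trace (common random numbers) ----------------------
        state = SparseGPState(Z, m, L, kernel)
        model = SVGPCRModel(
            state, rel, q_z, np.asarray(trace), config, K, A_count
        )
        trace.append(elbo(model, X, Y, mc_samples=S, eps=eval_eps))

        w = config.tol_window
        if it >= w:
            prev, cur = trace[-1 - w], trace[-1]
            if abs(cur - prev) / (abs(cur) + 1.0) < config.tol:
                break

    state = SparseGPState(Z, m, L, kernel)
    rel = update_q_R(q_z, Y, reliability_prior)
    trained = SVGPCRModel(state, rel, q_z, np.asarray(trace), config, K, A_count)

    # Vote-seeded coordinate ascent can never reach the symmetric "no signal"
    # configuration (uniform q(Z), flat-kernel prior GP): it is a stationary
    # point of the updates, so any tilt in the initialization is amplified
    # rather than undone.  On data whose annotations carry no class signal
    # that symmetric configuration holds a strictly higher bound than the
    # tilted local optimum the ascent converges to.  Evaluate both candidates
    # under the objective itself, with shared MC draws, and keep the winner.
    flat_kernel = KernelParams(1e-8, kernel.lengthscale)
    gp_flat = SparseGPState.prior(Z, K, flat_kernel)
    q_flat = TrueLabelPosterior(np.full((n, K), 1.0 / K), ids)
    rel_flat = update_q_R(q_flat, Y, reliability_prior)
    reference = SVGPCRModel(
        gp_flat, rel_flat, q_flat, np.asarray(trace), config, K, A_count
    )
    bound_trained = elbo(trained, X, Y, mc_samples=S, eps=eval_eps)
    bound_reference = elbo(reference, X, Y, mc_samples=S, eps=eval_eps)
    if bound_reference > bound_trained:
        log.info(
            "no-signal reference bound %.2f exceeds trained bound %.2f; "
            "returning the reference solution",
            bound_reference,
            bound_trained,
        )
        return reference
    return trained


def fit_svgp(
    X: np.ndarray,
    labels: np.ndarray,
    config: FitConfig | None = None,
    n_classes: int | None = None,
) -> SVGPCRModel:
    """Plain sparse-GP classifier on directly observed labels (1..K).

    Implemented as the crowd model with a single annotator whose Dirichlet
    prior is concentrated on the identity confusion matrix, so the labels are
    effectively trusted.
    """
    labels = np.asarray(labels, dtype=int)
    K = n_classes if n_classes is not None else int(labels.max())
    idx = np.arange(labels.size)
    Y = AnnotationSet(idx, np.zeros_like(idx), labels, K, 1)
    return fit(X, Y, config, n_classes=K, reliability_prior=perfect_annotator_prior(K))


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------


def predict(
    model: SVGPCRModel,
    X_new: np.ndarray,
    mc_samples: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Predictive true-class probabilities: MC-averaged softmax over q(f*)."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    mean, var = latent_marginals(model.gp, X_new)
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal((mc_samples, mean.shape[0], mean.shape[1]))
    f = mean[None] + np.sqrt(var)[None] * eps
    logp = f - logsumexp(f, axis=-1, keepdims=True)
    probs = np.exp(logp).mean(axis=0)
    return probs / probs.sum(axis=1, keepdims=True)


def predict_annotator(
    model: SVGPCRModel,
    X_new: np.ndarray,
    annotator: int,
    mc_samples: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """How a specific annotator would label new inputs.

    The true-class predictive distribution is pushed through the annotator's
    posterior-mean confusion matrix: out_i = sum_j mean(R^a)_ij p(z=j | x).
    """
    if not 0 <= int(annotator) < model.n_annotators:
        raise KeyError(
            f"unknown annotator id {annotator}; valid ids are "
            f"0..{model.n_annotators - 1}"
        )
    p_true = predict(model, X_new, mc_samples=mc_samples, seed=seed)
    Rbar = reliability_mean(model.reliabilities, int(annotator))
    out = p_true @ Rbar.T
    return out / out.sum(axis=1, keepdims=True)
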