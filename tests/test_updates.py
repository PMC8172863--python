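"""Closed-form variational updates: Dirichlet counts and categorical q(Z).

Oracles: count conservation by direct summation of q(Z) rows; the q(Z)
update against a plain-loop Bayes enumeration over classes; permutation
equivariance with explicitly permuted Monte-Carlo draws.
"""

import numpy as np
import pytest

from crowdgp import (
    AnnotationSet,
    ReliabilityState,
    TrueLabelPosterior,
    update_q_R,
    update_q_Z,
)
from crowdgp.crowd import expected_log_reliability


def test_update_q_r_empty_annotations():
    prior = ReliabilityState.uniform_prior(2, 3)
    q = TrueLabelPosterior(np.full((4, 3), 1.0 / 3.0))
    Y = AnnotationSet(np.array([], int), np.array([], int), np.array([], int), 3, 2)
    post = update_q_R(q, Y, prior)
    assert np.array_equal(post.posterior_alpha, prior.prior_alpha)


def test_update_q_r_single_annotation_example():
    # prior all-1; annotation y = class 1 on an instance with hard q(z) = class 2
    prior = ReliabilityState.uniform_prior(1, 3)
    q = TrueLabelPosterior(np.array([[0.0, 1.0, 0.0]]))
    Y = AnnotationSet.from_records([(0, 0, 1)], n_classes=3, n_annotators=1)
    post = update_q_R(q, Y, prior).posterior_alpha
    assert post[0, 0, 1] == pytest.approx(2.0)
    post[0, 0, 1] = 1.0
    assert np.allclose(post, 1.0)


def test_update_q_r_count_conservation(rng):
    # total added mass per annotator equals its annotation count exactly
    N, K, A = 40, 3, 4
    probs = rng.dirichlet(np.ones(K), size=N)
    q = TrueLabelPosterior(probs)
    records = []
    for n in range(N):
        for a in rng.choice(A, size=2, replace=False):
            records.append((n, int(a), int(rng.integers(1, K + 1))))
    Y = AnnotationSet.from_records(records, n_classes=K, n_annotators=A)
    prior = ReliabilityState.uniform_prior(A, K)
    post = update_q_R(q, Y, prior)
    added = (post.posterior_alpha - prior.prior_alpha).sum(axis=(1, 2))
    assert np.allclose(added, Y.counts_per_annotator(), atol=1e-9)


def test_update_q_r_unknown_instance_error():
    prior = ReliabilityState.uniform_prior(1, 2)
    q = TrueLabelPosterior(np.array([[0.5, 0.5]]), instance_ids=np.array([0]))
    Y = AnnotationSet.from_records([(7, 0, 1)], n_classes=2, n_annotators=1)
    with pytest.raises(ValueError, match="instance 7"):
        update_q_R(q, Y, prior)


# ---------------------------------------------------------------------------
# update_q_Z
# ---------------------------------------------------------------------------


def _flat_marginals(n, K, var=1e-10):
    return np.zeros((n, K)), np.full((n, K), var)


def test_update_q_z_uniform_without_annotations():
    n, K = 5, 3
    Y = AnnotationSet(np.array([], int), np.array([], int), np.array([], int), K, 1)
    rel = ReliabilityState.uniform_prior(1, K)
    q = update_q_Z(_flat_marginals(n, K), Y, rel, mc_samples=30, seed=0)
    assert np.allclose(q.probs, 1.0 / K, atol=1e-9)


def _enumeration_oracle(Y, rel, n, K, els):
    """Plain-loop Bayes enumeration: q(z=j) prop exp(els_j + sum E log r)."""
    out = np.zeros((n, K))
    for row in range(n):
        logs = els[row].copy()
        for i_rec in range(len(Y)):
            if Y.instance_ids[i_rec] == row:
                a = Y.annotator_ids[i_rec]
                lab = Y.labels[i_rec] - 1
                E = expected_log_reliability(rel, a)
                for j in range(K):
                    logs[j] += E[lab, j]
        p = np.exp(logs - logs.max())
        out[row] = p / p.sum()
    return out


def test_update_q_z_matches_enumeration_oracle(rng):
    n, K, A = 6, 3, 2
    alpha = rng.uniform(0.5, 6.0, size=(A, K, K))
    rel = ReliabilityState(np.ones((A, K, K)), alpha)
    records = [(0, 0, 1), (1, 0, 2), (1, 1, 3), (3, 1, 1), (4, 0, 2), (4, 1, 2)]
    Y = AnnotationSet.from_records(records, n_classes=K, n_annotators=A)
    mean = rng.standard_normal((n, K))
    var = rng.uniform(0.1, 1.0, size=(n, K))
    eps = rng.standard_normal((40, n, K))
    q = update_q_Z((mean, var), Y, rel, eps=eps)
    # the same MC draws feed the oracle's E[log softmax] term
    f = mean[None] + np.sqrt(var)[None] * eps
    els = np.zeros((n, K))
    for row in range(n):
        for j in range(K):
            vals = [f[s, row, j] - np.log(np.exp(f[s, row]).sum()) for s in range(40)]
            els[row, j] = np.mean(vals)
    expected = _enumeration_oracle(Y, rel, n, K, els)
    assert np.allclose(q.probs, expected, atol=1e-9)


def test_update_q_z_concentrates_on_annotated_class():
    # near-identity expected reliability, flat GP term
    K = 3
    alpha = np.ones((1, K, K)) * 0.5
    alpha[0, np.arange(K), np.arange(K)] = 200.0
    rel = ReliabilityState(np.ones((1, K, K)), alpha)
    Y = AnnotationSet.from_records([(0, 0, 2)], n_classes=K, n_annotators=1)
    q = update_q_Z(_flat_marginals(1, K), Y, rel, mc_samples=30, seed=1)
    assert q.probs[0].argmax() == 1
    assert q.probs[0, 1] > 0.95


def test_update_q_z_majority_beats_dissent():
    # two agreeing annotators outvote one dissenter of equal reliability
    K = 3
    alpha = np.ones((3, K, K))
    alpha[:, np.arange(K), np.arange(K)] = 8.0
    rel = ReliabilityState(np.ones((3, K, K)), alpha)
    Y = AnnotationSet.from_records(
        [(0, 0, 1), (0, 1, 1), (0, 2, 3)], n_classes=K, n_annotators=3
    )
    q = update_q_Z(_flat_marginals(1, K), Y, rel, mc_samples=30, seed=2)
    assert q.probs[0].argmax() == 0


def test_closed_form_updates_permutation_equivariant(rng):
    # relabeling classes by a permutation (and permuting the MC draws the
    # same way) permutes both closed-form updates exactly
    n, K, A = 5, 3, 2
    perm = np.array([2, 0, 1])  # new index of each old class
    records = [(0, 0, 1), (1, 1, 2), (2, 0, 3), (3, 1, 1), (4, 0, 2)]
    Y = AnnotationSet.from_records(records, n_classes=K, n_annotators=A)
    Yp = AnnotationSet(
        Y.instance_ids, Y.annotator_ids, perm[Y.label_index] + 1, K, A
    )
    alpha = rng.uniform(0.5, 3.0, size=(A, K, K))
    rel = ReliabilityState(np.ones((A, K, K)), alpha)
    # permute rows and columns consistently: alpha'[a, perm[i], perm[j]] = alpha[a, i, j]
    ap = np.empty_like(alpha)
    ap[:, perm[:, None], perm[None, :]] = alpha
    rel_p = ReliabilityState(np.ones((A, K, K)), ap)

    probs = rng.dirichlet(np.ones(K), size=n)
    q = TrueLabelPosterior(probs)
    qp_probs = np.empty_like(probs)
    qp_probs[:, perm] = probs
    q_p = TrueLabelPosterior(qp_probs)

    prior = ReliabilityState.uniform_prior(A, K)
    post = update_q_R(q, Y, prior).posterior_alpha
    post_p = update_q_R(q_p, Yp, prior).posterior_alpha
    expected = np.empty_like(post)
    expected[:, perm[:, None], perm[None, :]] = post
    assert np.allclose(post_p, expected, atol=1e-12)

    mean = rng.standard_normal((n, K))
    var = rng.uniform(0.2, 1.0, size=(n, K))
    eps = rng.standard_normal((25, n, K))
    qz = update_q_Z((mean, var), Y, rel, eps=eps).probs
    mean_p = np.empty_like(mean)
    var_p = np.empty_like(var)
    eps_p = np.empty_like(eps)
    mean_p[:, perm] = mean
    var_p[:, perm] = var
    eps_p[:, :, perm] = eps
    qz_p = update_q_Z((mean_p, var_p), Yp, rel_p, eps=eps_p).probs
    expected_z = np.empty_like(qz)
    expected_z[:, perm] = qz
    assert np.allclose(qz_p, expected_z, atol=1e-12)
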