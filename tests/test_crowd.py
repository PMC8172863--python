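"""Crowd likelihood primitives: confusion matrices, softmax link, Dirichlet."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import digamma
from scipy.stats import beta as beta_dist

from crowdgp import (
    AnnotationSet,
    ReliabilityState,
    TrueLabelPosterior,
    annotation_likelihood,
    dirichlet_kl,
    expected_log_reliability,
    reliability_mean,
    softmax_link,
)


def one_hot(i, K):
    v = np.zeros(K)
    v[i] = 1.0
    return v


# ---------------------------------------------------------------------------
# annotation_likelihood
# ---------------------------------------------------------------------------


def test_annotation_likelihood_identity_examples():
    I3 = np.eye(3)
    assert annotation_likelihood(one_hot(0, 3), one_hot(0, 3), I3) == 1.0
    assert annotation_likelihood(one_hot(1, 3), one_hot(0, 3), I3) == 0.0


def test_annotation_likelihood_selects_entry():
    R = np.array([[0.6, 0.3], [0.4, 0.7]])
    R[0, 1] = 0.3
    assert annotation_likelihood(one_hot(0, 2), one_hot(1, 2), R) == pytest.approx(0.3)


def test_annotation_likelihood_sums_to_one(rng):
    # marginalizing the reported label gives 1 (column stochasticity)
    K = 4
    R = rng.dirichlet(np.ones(K), size=K).T  # columns are simplex points
    for j in range(K):
        total = sum(
            annotation_likelihood(one_hot(i, K), one_hot(j, K), R) for i in range(K)
        )
        assert total == pytest.approx(1.0, abs=1e-9)


def test_annotation_likelihood_rejects_non_stochastic():
    R = np.eye(3)
    R[0, 1] = 0.5
    with pytest.raises(ValueError, match="column 1"):
        annotation_likelihood(one_hot(0, 3), one_hot(0, 3), R)


def test_annotation_likelihood_rejects_bad_onehot():
    with pytest.raises(ValueError, match="one-hot"):
        annotation_likelihood(np.array([0.5, 0.5, 0.0]), one_hot(0, 3), np.eye(3))


# ---------------------------------------------------------------------------
# softmax_link
# ---------------------------------------------------------------------------


def test_softmax_uniform_on_constant():
    assert np.allclose(softmax_link(np.zeros(3)), 1.0 / 3.0)
    assert np.allclose(softmax_link(np.full(3, 17.2)), 1.0 / 3.0)


def test_softmax_shift_invariance(rng):
    f = rng.standard_normal(5)
    assert np.allclose(softmax_link(f), softmax_link(f + 123.4), atol=1e-12)


def test_softmax_derived_example():
    out = softmax_link(np.array([1.0, 0.0, 0.0]))
    e = np.e
    assert out[0] == pytest.approx(e / (e + 2.0), abs=1e-9)
    assert np.round(out, 6).tolist() == [0.576117, 0.211942, 0.211942]


def test_softmax_is_probability_vector(rng):
    for _ in range(25):
        out = softmax_link(rng.standard_normal(4) * 50)
        assert np.all(out >= 0) and out.sum() == pytest.approx(1.0, abs=1e-9)


def test_softmax_monotone_in_own_logit():
    base = np.array([0.0, 1.0, -1.0])
    lo = softmax_link(base)[0]
    base[0] += 0.5
    assert softmax_link(base)[0] > lo


def test_softmax_overflow_safe_and_nan_error():
    out = softmax_link(np.array([1e4, 0.0]))
    assert np.isfinite(out).all() and out[0] == pytest.approx(1.0)
    with pytest.raises(ValueError, match="NaN"):
        softmax_link(np.array([np.nan, 0.0]))


# ---------------------------------------------------------------------------
# reliability state / Dirichlet algebra
# ---------------------------------------------------------------------------


def test_expected_log_reliability_uniform_column():
    state = ReliabilityState.uniform_prior(1, 3)
    E = expected_log_reliability(state, 0)
    # psi(1) - psi(3) = -(1/1 + 1/2) = -1.5
    assert np.allclose(E, -1.5, atol=1e-12)


def test_expected_log_reliability_equal_entries_on_symmetric_column():
    alpha = np.full((1, 4, 4), 2.7)
    E = expected_log_reliability(ReliabilityState(alpha), 0)
    assert np.allclose(E, E[0, 0])
    assert np.all(E <= 0)


def test_expected_log_reliability_concentration_limit():
    alpha = np.ones((1, 3, 3))
    alpha[0, :, 0] = [1e8, 1e-8, 1e-8]
    E = expected_log_reliability(ReliabilityState(alpha), 0)
    assert E[0, 0] == pytest.approx(0.0, abs=1e-6)
    assert E[1, 0] < -1e6


def test_jensen_inequality_log_reliability(rng):
    for _ in range(20):
        alpha = rng.uniform(0.2, 5.0, size=(1, 3, 3))
        state = ReliabilityState(alpha)
        E = expected_log_reliability(state, 0)
        logmean = np.log(reliability_mean(state, 0))
        assert np.all(E <= logmean + 1e-12)


def test_reliability_mean_examples():
    state = ReliabilityState.uniform_prior(2, 3)
    assert np.allclose(reliability_mean(state, 1), 1.0 / 3.0)
    alpha = np.ones((1, 3, 3))
    alpha[0, :, 0] = [3.0, 1.0, 1.0]
    R = reliability_mean(ReliabilityState(alpha), 0)
    assert np.allclose(R[:, 0], [0.6, 0.2, 0.2])
    assert np.allclose(R.sum(axis=0), 1.0)


def test_reliability_mean_near_identity_after_consistent_annotations(rng):
    # 500 perfect annotations starting from the alpha=1 prior
    prior = ReliabilityState.uniform_prior(1, 3)
    post = prior.prior_alpha.copy()
    labels = rng.integers(0, 3, size=500)
    for z in labels:
        post[0, z, z] += 1.0
    R = reliability_mean(ReliabilityState(prior.prior_alpha, post), 0)
    off = R - np.diag(np.diag(R))
    assert off.max() < 0.05


def test_unknown_annotator_raises():
    state = ReliabilityState.uniform_prior(2, 3)
    with pytest.raises(KeyError, match="annotator"):
        reliability_mean(state, 5)


def test_dirichlet_parameters_must_be_positive():
    with pytest.raises(ValueError, match="positive"):
        ReliabilityState(np.zeros((1, 2, 2)))


def test_dirichlet_kl_zero_at_equality_and_nonnegative(rng):
    alpha = rng.uniform(0.5, 4.0, size=(2, 3, 3))
    assert dirichlet_kl(alpha, alpha) == pytest.approx(0.0, abs=1e-10)
    beta = alpha + rng.uniform(0, 2, size=alpha.shape)
    assert dirichlet_kl(beta, alpha) > 0


def test_dirichlet_kl_matches_numerical_integration():
    # independent oracle: K=2 columns are Beta distributions; integrate
    # q log(q/p) numerically
    q_a = np.array([3.0, 2.0])
    p_a = np.array([1.0, 1.0])

    def integrand(x):
        q = beta_dist.pdf(x, q_a[0], q_a[1])
        p = beta_dist.pdf(x, p_a[0], p_a[1])
        return q * np.log(q / p)

    expected, _ = quad(integrand, 1e-9, 1 - 1e-9)
    got = dirichlet_kl(q_a, p_a)
    assert got == pytest.approx(expected, abs=1e-6)


def test_dirichlet_kl_shape_mismatch():
    with pytest.raises(ValueError, match="match"):
        dirichlet_kl(np.ones((1, 2, 2)), np.ones((1, 3, 3)))


# ---------------------------------------------------------------------------
# AnnotationSet
# ---------------------------------------------------------------------------


def test_annotation_set_roundtrip_and_accessors():
    Y = AnnotationSet.from_records(
        [(0, 0, 1), (0, 1, 2), (2, 0, 3)], n_classes=3, n_annotators=2
    )
    assert len(Y) == 3
    assert Y.annotated_instances.tolist() == [0, 2]
    assert Y.label_index.tolist() == [0, 1, 2]
    assert Y.counts_per_annotator().tolist() == [2, 1]
    df = Y.to_dataframe()
    back = AnnotationSet.from_dataframe(df, n_classes=3)
    assert np.array_equal(back.labels, Y.labels)
    sub = Y.subset_instances([0])
    assert len(sub) == 2 and set(sub.instance_ids.tolist()) == {0}


def test_annotation_set_validation():
    with pytest.raises(ValueError, match="duplicate"):
        AnnotationSet.from_records([(0, 0, 1), (0, 0, 2)], n_classes=2)
    with pytest.raises(ValueError, match="1..2"):
        AnnotationSet.from_records([(0, 0, 3)], n_classes=2)
    with pytest.raises(ValueError, match="n_annotators"):
        AnnotationSet(np.array([0]), np.array([4]), np.array([1]), 2, n_annotators=2)


# ---------------------------------------------------------------------------
# TrueLabelPosterior
# ---------------------------------------------------------------------------


def test_true_label_posterior_validation_and_maps():
    with pytest.raises(ValueError, match="sum to 1"):
        TrueLabelPosterior(np.array([[0.5, 0.4]]))
    q = TrueLabelPosterior(np.array([[0.5, 0.5], [0.2, 0.8]]))
    assert q.map_labels().tolist() == [1, 2]  # tie -> smallest class
    uniform = TrueLabelPosterior(np.full((4, 3), 1.0 / 3.0))
    assert uniform.entropy() == pytest.approx(4 * np.log(3.0), abs=1e-12)
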