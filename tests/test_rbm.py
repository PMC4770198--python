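"""Energy-model correctness against exact enumeration oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.special import logsumexp

from rbpdeep.rbm import (
    CdConfig,
    RbmParameters,
    RsmParameters,
    cd_update,
    conditional_hidden,
    conditional_visible,
    exact_log_partition,
    exact_visible_marginal,
    free_energy,
    init_rbm,
    rbm_energy,
    rsm_cd_update,
    rsm_conditional_hidden,
    rsm_conditional_words,
    rsm_energy,
    rsm_free_energy,
    train_rbm,
)


def _random_rbm(rng, m, n, scale=0.5):
    return RbmParameters(
        W=rng.normal(0, scale, (m, n)),
        b=rng.normal(0, scale, m),
        c=rng.normal(0, scale, n),
    )


def _states(n):
    return [np.array(s, dtype=float) for s in itertools.product((0, 1), repeat=n)]


def test_rbm_energy_direct_substitution():
    params = RbmParameters(W=np.array([[1.0], [2.0]]), b=np.array([0.5, -0.5]), c=np.array([1.0]))
    assert rbm_energy(np.array([1, 1]), np.array([1]), params) == pytest.approx(-4.0)
    zero = RbmParameters(W=np.zeros((2, 1)), b=np.zeros(2), c=np.zeros(1))
    for v in _states(2):
        for h in _states(1):
            assert rbm_energy(v, h, zero) == 0.0


def test_joint_density_normalizes():
    rng = np.random.default_rng(1)
    for m, n in [(3, 2), (4, 3), (7, 7)]:
        params = _random_rbm(rng, m, n)
        log_z = exact_log_partition(params)
        total = sum(
            np.exp(-rbm_energy(v, h, params) - log_z)
            for v in _states(m)
            for h in _states(n)
        )
        assert total == pytest.approx(1.0, abs=1e-10)


def test_exact_log_partition_two_enumeration_orders():
    rng = np.random.default_rng(2)
    zero = RbmParameters(W=np.zeros((3, 2)), b=np.zeros(3), c=np.zeros(2))
    assert exact_log_partition(zero) == pytest.approx(np.log(32))
    for _ in range(5):
        params = _random_rbm(rng, 5, 4)
        # independent order: enumerate (v, h) jointly instead of via F(v)
        direct = logsumexp(
            [-rbm_energy(v, h, params) for v in _states(5) for h in _states(4)]
        )
        assert exact_log_partition(params) == pytest.approx(direct, abs=1e-8)
        assert exact_visible_marginal(params).sum() == pytest.approx(1.0, abs=1e-10)
    big = RbmParameters(W=np.zeros((25, 2)), b=np.zeros(25), c=np.zeros(2))
    with pytest.raises(ValueError, match="enumerat"):
        exact_log_partition(big)


def test_conditionals_match_bayes_rule():
    rng = np.random.default_rng(3)
    params = _random_rbm(rng, 4, 3)
    log_z = exact_log_partition(params)
    for v in _states(4):
        joint = np.array([np.exp(-rbm_energy(v, h, params) - log_z) for h in _states(3)])
        post = joint / joint.sum()
        marginal_h1 = np.array(
            [sum(p for h, p in zip(_states(3), post) if h[j] == 1) for j in range(3)]
        )
        assert np.allclose(conditional_hidden(v, params), marginal_h1, atol=1e-10)
    # symmetric check for visibles
    for h in _states(3):
        joint = np.array([np.exp(-rbm_energy(v, h, params) - log_z) for v in _states(4)])
        post = joint / joint.sum()
        marginal_v1 = np.array(
            [sum(p for v, p in zip(_states(4), post) if v[i] == 1) for i in range(4)]
        )
        assert np.allclose(conditional_visible(h, params), marginal_v1, atol=1e-10)


def test_conditional_monotone_in_weight():
    params = RbmParameters(W=np.zeros((2, 2)), b=np.zeros(2), c=np.zeros(2))
    v = np.array([1.0, 0.0])
    last = 0.0
    for w in np.linspace(0, 3, 7):
        p = conditional_hidden(v, RbmParameters(W=np.array([[w, 0.0], [0.0, 0.0]]), b=params.b, c=params.c))[0]
        assert p >= last
        last = p


def test_free_energy_identities():
    rng = np.random.default_rng(4)
    zero = RbmParameters(W=np.zeros((3, 5)), b=np.zeros(3), c=np.zeros(5))
    assert free_energy(np.zeros(3), zero) == pytest.approx(-5 * np.log(2))
    params = _random_rbm(rng, 4, 3)
    log_z = exact_log_partition(params)
    marginal = exact_visible_marginal(params)
    for idx, v in enumerate(_states(4)):
        assert np.exp(-free_energy(v, params) - log_z) == pytest.approx(
            marginal[idx], abs=1e-10
        )
    # shifting every hidden bias by delta changes F by the analytic softplus sum
    delta = 0.37
    shifted = RbmParameters(W=params.W, b=params.b, c=params.c + delta)
    v = np.array([1.0, 0.0, 1.0, 1.0])
    act = v @ params.W + params.c
    expected_shift = -(np.logaddexp(0, act + delta) - np.logaddexp(0, act)).sum()
    assert free_energy(v, shifted) - free_energy(v, params) == pytest.approx(
        expected_shift, abs=1e-10
    )


# ---------------------------------------------------------------------------
# replicated softmax
# ---------------------------------------------------------------------------

def _random_rsm(rng, K, n, scale=0.5):
    return RsmParameters(
        W=rng.normal(0, scale, (K, n)),
        b=rng.normal(0, scale, K),
        c=rng.normal(0, scale, n),
    )


def test_rsm_energy_identities():
    rng = np.random.default_rng(5)
    zero = RsmParameters(W=np.zeros((3, 2)), b=np.zeros(3), c=np.zeros(2))
    assert rsm_energy(np.array([1, 1, 0]), np.array([1, 0]), zero, 2) == 0.0
    params = _random_rsm(rng, 4, 3)
    counts = np.array([2.0, 0.0, 1.0, 3.0])
    h = np.array([1.0, 0.0, 1.0])
    e1 = rsm_energy(counts, h, params, 6)
    assert rsm_energy(2 * counts, h, params, 12) == pytest.approx(2 * e1)
    with pytest.raises(ValueError, match="D"):
        rsm_energy(counts, h, params, 5)


def test_rsm_single_word_reduces_to_rbm():
    """A one-word document (D=1) is an ordinary RBM with a one-hot visible."""
    rng = np.random.default_rng(6)
    params = _random_rsm(rng, 5, 3)
    as_rbm = RbmParameters(W=params.W, b=params.b, c=params.c)
    for k in range(5):
        one_hot = np.eye(5)[k]
        for h in _states(3):
            assert rsm_energy(one_hot, h, params, 1) == pytest.approx(
                rbm_energy(one_hot, h, as_rbm), abs=1e-12
            )
    assert np.allclose(
        rsm_conditional_hidden(np.eye(5), params, np.ones(5)),
        conditional_hidden(np.eye(5), as_rbm),
    )


def _all_count_vectors(K, D):
    """All multisets of D words over a K-word dictionary."""
    for combo in itertools.combinations_with_replacement(range(K), D):
        vec = np.zeros(K)
        for k in combo:
            vec[k] += 1
        yield vec


def test_rsm_conditionals_match_enumeration():
    rng = np.random.default_rng(7)
    K, D, n = 3, 2, 2
    params = _random_rsm(rng, K, n)
    zero = RsmParameters(W=np.zeros((K, n)), b=np.zeros(K), c=np.zeros(n))
    assert np.allclose(rsm_conditional_hidden(np.array([1.0, 1.0, 0.0]), zero, 2), 0.5)
    assert np.allclose(rsm_conditional_words(np.array([1.0, 0.0]), zero), 1 / K)
    for counts in _all_count_vectors(K, D):
        weights = np.array(
            [np.exp(-rsm_energy(counts, np.array(h), params, D)) for h in _states(n)]
        )
        post = weights / weights.sum()
        marginal = np.array(
            [sum(p for h, p in zip(_states(n), post) if h[j] == 1) for j in range(n)]
        )
        assert np.allclose(rsm_conditional_hidden(counts, params, D), marginal, atol=1e-10)
    # word conditional normalizes and matches the softmax definition
    for h in _states(n):
        dist = rsm_conditional_words(np.array(h), params)
        assert dist.sum() == pytest.approx(1.0, abs=1e-12)
        logits = params.W @ np.array(h) + params.b
        assert np.allclose(dist, np.exp(logits) / np.exp(logits).sum())


def test_rsm_word_order_invariance():
    """Energy and conditionals depend on documents only through counts:
    any two orderings of the same words give identical count vectors and
    hence identical model quantities (checked via the free energy)."""
    rng = np.random.default_rng(8)
    params = _random_rsm(rng, 4, 3)
    words = [0, 2, 2, 3, 1]
    counts = np.bincount(words, minlength=4).astype(float)
    rng.shuffle(words)
    counts_shuffled = np.bincount(words, minlength=4).astype(float)
    assert np.array_equal(counts, counts_shuffled)
    assert rsm_free_energy(counts, params) == pytest.approx(
        float(rsm_free_energy(counts_shuffled, params))
    )


# ---------------------------------------------------------------------------
# contrastive divergence
# ---------------------------------------------------------------------------

def test_cd_update_deterministic_and_validated():
    rng = np.random.default_rng(9)
    params = _random_rbm(rng, 6, 3, scale=0.1)
    batch = (np.random.default_rng(1).random((20, 6)) < 0.5).astype(float)
    upd1 = cd_update(params, batch, 0.05, np.random.default_rng(42))
    upd2 = cd_update(params, batch, 0.05, np.random.default_rng(42))
    for f in ("W", "b", "c"):
        assert np.array_equal(getattr(upd1, f), getattr(upd2, f))
    with pytest.raises(ValueError, match="learning rate"):
        cd_update(params, batch, -0.1, rng)


def test_cd_fixed_point_on_model_samples():
    """Data drawn from the model's own distribution gives a zero expected
    update (checked to three standard errors over 200 seeded updates)."""
    rng = np.random.default_rng(10)
    params = _random_rbm(rng, 5, 3, scale=0.4)
    marginal = exact_visible_marginal(params)
    states = np.array(_states(5))
    updates = []
    for rep in range(200):
        r = np.random.default_rng(1000 + rep)
        idx = r.choice(len(states), size=30, p=marginal)
        batch = states[idx]
        new = cd_update(params, batch, 1.0, r)  # lr 1 -> update equals gradient
        updates.append(np.concatenate([(new.W - params.W).ravel(), new.b - params.b, new.c - params.c]))
    updates = np.array(updates)
    mean = updates.mean(axis=0)
    se = updates.std(axis=0, ddof=1) / np.sqrt(len(updates))
    assert np.all(np.abs(mean) <= 3 * se + 1e-12)


def test_exact_gradient_cd_increases_likelihood():
    """With the exact negative phase, CD is true gradient ascent: the
    training log-likelihood is non-decreasing on a 6x3 RBM."""
    rng = np.random.default_rng(11)
    data = (rng.random((40, 6)) < rng.random(6)).astype(float)
    params = init_rbm(6, 3, rng, sigma=0.01)

    def log_likelihood(p):
        return float(-free_energy(data, p).mean() - exact_log_partition(p))

    ll = [log_likelihood(params)]
    for _ in range(200):
        params = cd_update(params, data, 0.05, rng, exact_negative=True)
        ll.append(log_likelihood(params))
    diffs = np.diff(ll)
    assert np.all(diffs >= -1e-10)
    assert ll[-1] > ll[0]


def test_rsm_cd_deterministic_and_preserves_D():
    rng = np.random.default_rng(12)
    params = _random_rsm(rng, 6, 3, scale=0.1)
    batch = np.random.default_rng(2).integers(0, 3, (15, 6)).astype(float)
    upd1 = rsm_cd_update(params, batch, 0.05, np.random.default_rng(7))
    upd2 = rsm_cd_update(params, batch, 0.05, np.random.default_rng(7))
    for f in ("W", "b", "c"):
        assert np.array_equal(getattr(upd1, f), getattr(upd2, f))


def test_train_rbm_reduces_reconstruction_error():
    from rbpdeep.rbm import reconstruction_cross_entropy

    rng = np.random.default_rng(13)
    # correlated binary data: two prototype patterns plus noise
    protos = np.array([[1, 1, 1, 0, 0, 0, 1, 0], [0, 0, 0, 1, 1, 1, 0, 1]], dtype=float)
    data = protos[rng.integers(0, 2, 200)]
    flip = rng.random(data.shape) < 0.05
    data = np.abs(data - flip)
    init = init_rbm(8, 4, np.random.default_rng(0), sigma=0.01)
    trained = train_rbm(data, 4, CdConfig(epochs=30, batch_size=50), np.random.default_rng(0))
    assert reconstruction_cross_entropy(data, trained) < reconstruction_cross_entropy(
        data, init
    )
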