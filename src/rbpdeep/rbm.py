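"""Energy models and training: binary restricted Boltzmann machines,
the replicated softmax variant over word-count vectors, contrastive
divergence, and exact enumeration oracles for small instances.

A binary RBM over visible v in {0,1}^m and hidden h in {0,1}^n has energy

    E(v, h) = - v' W h - b'v - c'h

and joint density p(v, h) = exp(-E) / Z.  The replicated softmax ties the
weights of D softmax visible units (one per word of a document), so the
energy depends on a document only through its count vector v_hat:

    E(V, h) = - h' W' v_hat - b' v_hat - D c'h,

with the hidden bias scaled by the document size D.  Both models share
closed-form conditionals (logistic for hidden units; logistic / softmax
for visibles) and a softplus free energy used for scoring.

All stochastic operations draw from an explicit ``numpy.random.Generator``
so a single integer seed yields a deterministic training trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import expit, logsumexp, softmax

MAX_ENUMERATION_UNITS = 20


@dataclass(frozen=True)
class RbmParameters:
    """Binary RBM parameters: W (m, n), visible bias b (m), hidden bias c (n)."""

    W: np.ndarray
    b: np.ndarray
    c: np.ndarray

    def __post_init__(self) -> None:
        W, b, c = map(np.asarray, (self.W, self.b, self.c))
        if W.shape != (b.shape[0], c.shape[0]):
            raise ValueError(f"inconsistent shapes W{W.shape} b{b.shape} c{c.shape}")
        for a in (W, b, c):
            if not np.isfinite(a).all():
                raise ValueError("non-finite parameter entries")

    @property
    def m(self) -> int:
        return self.b.shape[0]

    @property
    def n(self) -> int:
        return self.c.shape[0]


@dataclass(frozen=True)
class RsmParameters:
    """Replicated-softmax parameters: W (K, n), word bias b (K), topic bias c (n).

    Weights are tied across word positions, so energies and conditionals
    are functions of count vectors only.
    """

    W: np.ndarray
    b: np.ndarray
    c: np.ndarray

    def __post_init__(self) -> None:
        W, b, c = map(np.asarray, (self.W, self.b, self.c))
        if W.shape != (b.shape[0], c.shape[0]):
            raise ValueError(f"inconsistent shapes W{W.shape} b{b.shape} c{c.shape}")
        for a in (W, b, c):
            if not np.isfinite(a).all():
                raise ValueError("non-finite parameter entries")

    @property
    def K(self) -> int:
        return self.b.shape[0]

    @property
    def n(self) -> int:
        return self.c.shape[0]


def init_rbm(m: int, n: int, rng: np.random.Generator, sigma: float = 0.01) -> RbmParameters:
    return RbmParameters(W=rng.normal(0.0, sigma, (m, n)), b=np.zeros(m), c=np.zeros(n))


def init_rsm(K: int, n: int, rng: np.random.Generator, sigma: float = 0.01) -> RsmParameters:
    return RsmParameters(W=rng.normal(0.0, sigma, (K, n)), b=np.zeros(K), c=np.zeros(n))


# ---------------------------------------------------------------------------
# energies and conditionals
# ---------------------------------------------------------------------------

def rbm_energy(v: np.ndarray, h: np.ndarray, params: RbmParameters) -> float:
    """E(v, h) = -v'Wh - b'v - c'h."""
    v = np.asarray(v, dtype=float)
    h = np.asarray(h, dtype=float)
    if v.shape[-1] != params.m or h.shape[-1] != params.n:
        raise ValueError("state shapes do not match parameters")
    return float(-(v @ params.W @ h) - params.b @ v - params.c @ h)


def conditional_hidden(v: np.ndarray, params: RbmParameters) -> np.ndarray:
    """p(h_j = 1 | v) = logistic(sum_i w_ij v_i + c_j); supports batches."""
    v = np.asarray(v, dtype=float)
    if v.shape[-1] != params.m:
        raise ValueError("visible shape does not match parameters")
    return expit(v @ params.W + params.c)


def conditional_visible(h: np.ndarray, params: RbmParameters) -> np.ndarray:
    """p(v_i = 1 | h) = logistic(sum_j w_ij h_j + b_i); supports batches."""
    h = np.asarray(h, dtype=float)
    if h.shape[-1] != params.n:
        raise ValueError("hidden shape does not match parameters")
    return expit(h @ params.W.T + params.b)


def free_energy(v: np.ndarray, params: RbmParameters) -> np.ndarray:
    """F(v) = -b'v - sum_j softplus(c_j + (W'v)_j), batched over rows."""
    v = np.atleast_2d(np.asarray(v, dtype=float))
    if v.shape[-1] != params.m:
        raise ValueError("visible shape does not match parameters")
    act = v @ params.W + params.c
    out = -(v @ params.b) - np.logaddexp(0.0, act).sum(axis=-1)
    return out if out.shape[0] > 1 else out[0]


def rsm_energy(counts: np.ndarray, h: np.ndarray, params: RsmParameters, D: int) -> float:
    """E(V, h) = -h'W'v_hat - b'v_hat - D c'h, with v_hat the count vector."""
    counts = np.asarray(counts, dtype=float)
    h = np.asarray(h, dtype=float)
    if counts.shape[-1] != params.K or h.shape[-1] != params.n:
        raise ValueError("state shapes do not match parameters")
    if int(round(counts.sum())) != D:
        raise ValueError(f"D={D} does not match count total {counts.sum()}")
    return float(-(h @ params.W.T @ counts) - params.b @ counts - D * (params.c @ h))


def rsm_conditional_hidden(
    counts: np.ndarray, params: RsmParameters, D: np.ndarray | int | None = None
) -> np.ndarray:
    """p(h_j = 1 | V) = logistic(sum_k w_j^k v_hat^k + D c_j), batched.

    ``D`` defaults to the row sums of ``counts``.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape[-1] != params.K:
        raise ValueError("count shape does not match parameters")
    if D is None:
        D = counts.sum(axis=-1)
    D = np.asarray(D, dtype=float)
    return expit(counts @ params.W + np.multiply.outer(D, params.c))


def rsm_conditional_words(h: np.ndarray, params: RsmParameters) -> np.ndarray:
    """softmax over words k of (sum_j w_j^k h_j + b^k); batched over rows of h."""
    h = np.asarray(h, dtype=float)
    if h.shape[-1] != params.n:
        raise ValueError("hidden shape does not match parameters")
    return softmax(h @ params.W.T + params.b, axis=-1)


def rsm_free_energy(
    counts: np.ndarray, params: RsmParameters, D: np.ndarray | int | None = None
) -> np.ndarray:
    """F(V) = -b'v_hat - sum_j softplus(D c_j + (W'v_hat)_j), batched."""
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    if D is None:
        D = counts.sum(axis=-1)
    D = np.atleast_1d(np.asarray(D, dtype=float))
    act = counts @ params.W + np.multiply.outer(D, params.c)
    out = -(counts @ params.b) - np.logaddexp(0.0, act).sum(axis=-1)
    return out if out.shape[0] > 1 else out[0]


# ---------------------------------------------------------------------------
# exact enumeration oracles (small instances only)
# ---------------------------------------------------------------------------

def _all_binary_states(n: int) -> np.ndarray:
    if n > MAX_ENUMERATION_UNITS:
        raise ValueError(f"refusing to enumerate 2**{n} states")
    return ((np.arange(2**n)[:, None] >> np.arange(n)[::-1]) & 1).astype(float)


def exact_log_partition(params: RbmParameters) -> float:
    """log Z by enumerating visible states and summing exp(-F(v)).

    Guarded to m <= 20 visible units; the test suite cross-checks it
    against the independent (v, h) double enumeration.
    """
    if params.m > MAX_ENUMERATION_UNITS:
        raise ValueError("instance too large for exact enumeration")
    v = _all_binary_states(params.m)
    return float(logsumexp(-free_energy(v, params)))


def exact_visible_marginal(params: RbmParameters) -> np.ndarray:
    """p(v) for every visible state, in _all_binary_states order."""
    v = _all_binary_states(params.m)
    log_p = -free_energy(v, params) - exact_log_partition(params)
    return np.exp(np.atleast_1d(log_p))


def exact_moments(params: RbmParameters) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact model expectations (E[v h'], E[v], E[h]) by enumeration."""
    v = _all_binary_states(params.m)
    p = exact_visible_marginal(params)
    h_prob = conditional_hidden(v, params)
    ev = p @ v
    eh = p @ h_prob
    evh = (v * p[:, None]).T @ h_prob
    return evh, ev, eh


# ---------------------------------------------------------------------------
# contrastive divergence
# ---------------------------------------------------------------------------

def _bernoulli(p: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return (rng.random(p.shape) < p).astype(float)


def cd_update(
    params: RbmParameters,
    minibatch: np.ndarray,
    learning_rate: float,
    rng: np.random.Generator,
    k_steps: int = 1,
    weight_decay: float = 0.0,
    exact_negative: bool = False,
) -> RbmParameters:
    """One contrastive-divergence parameter update for a binary RBM.

    The positive phase uses the data with mean-field hidden activations;
    the negative phase runs ``k_steps`` of blocked Gibbs sampling from the
    data (mean-field on the final half-step).  With ``exact_negative`` the
    negative statistics are the exact model moments by enumeration, making
    the update the true likelihood gradient (test oracle for small RBMs).
    """
    if learning_rate <= 0:
        raise ValueError("learning rate must be positive")
    v0 = np.atleast_2d(np.asarray(minibatch, dtype=float))
    B = v0.shape[0]
    h0 = conditional_hidden(v0, params)
    if exact_negative:
        neg_W, neg_b, neg_c = exact_moments(params)
    else:
        h_sample = _bernoulli(h0, rng)
        vk = v0
        for _ in range(k_steps):
            vk = conditional_visible(h_sample, params)
            v_sample = _bernoulli(vk, rng)
            h_sample = _bernoulli(conditional_hidden(v_sample, params), rng)
            vk = v_sample
        hk = conditional_hidden(vk, params)
        neg_W = vk.T @ hk / B
        neg_b = vk.mean(axis=0)
        neg_c = hk.mean(axis=0)
    grad_W = v0.T @ h0 / B - neg_W - weight_decay * params.W
    grad_b = v0.mean(axis=0) - neg_b
    grad_c = h0.mean(axis=0) - neg_c
    return RbmParameters(
        W=params.W + learning_rate * grad_W,
        b=params.b + learning_rate * grad_b,
        c=params.c + learning_rate * grad_c,
    )


def rsm_cd_update(
    params: RsmParameters,
    minibatch: np.ndarray,
    learning_rate: float,
    rng: np.random.Generator,
    k_steps: int = 1,
    weight_decay: float = 0.0,
    precondition_hidden_bias: bool = True,
) -> RsmParameters:
    """One CD update for the replicated softmax.

    The Gibbs step resamples exactly D words per document from the softmax
    word distribution, preserving each document's size.  Because the
    hidden-bias gradient carries a factor of D, its raw magnitude scales
    with document size; ``precondition_hidden_bias`` divides it by the
    batch-mean D (a diagonal preconditioner that leaves fixed points
    unchanged) so one learning rate works across document sizes.
    """
    if learning_rate <= 0:
        raise ValueError("learning rate must be positive")
    v0 = np.atleast_2d(np.asarray(minibatch, dtype=float))
    B = v0.shape[0]
    D = v0.sum(axis=-1)
    h0 = rsm_conditional_hidden(v0, params, D)
    h_sample = _bernoulli(h0, rng)
    vk = v0
    for _ in range(k_steps):
        word_p = rsm_conditional_words(h_sample, params)
        vk = np.stack(
            [rng.multinomial(int(d), p) for d, p in zip(D, word_p)]
        ).astype(float)
        h_sample = _bernoulli(rsm_conditional_hidden(vk, params, D), rng)
    hk = rsm_conditional_hidden(vk, params, D)
    grad_W = (v0.T @ h0 - vk.T @ hk) / B - weight_decay * params.W
    grad_b = (v0 - vk).mean(axis=0)
    grad_c = (D[:, None] * (h0 - hk)).mean(axis=0)
    if precondition_hidden_bias:
        grad_c = grad_c / max(float(D.mean()), 1.0)
    return RsmParameters(
        W=params.W + learning_rate * grad_W,
        b=params.b + learning_rate * grad_b,
        c=params.c + learning_rate * grad_c,
    )


# ---------------------------------------------------------------------------
# epoch-level training with momentum
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CdConfig:
    """Contrastive-divergence hyperparameters (standard DBN practice)."""

    epochs: int = 20
    batch_size: int = 100
    learning_rate: float = 0.05
    k_steps: int = 1
    momentum_initial: float = 0.5
    momentum_final: float = 0.9
    momentum_switch_epoch: int = 5
    weight_decay: float = 2e-4
    init_sigma: float = 0.01


def train_rbm(
    data: np.ndarray,
    n_hidden: int,
    config: CdConfig,
    rng: np.random.Generator,
) -> RbmParameters:
    """Train a binary RBM on (possibly real-valued in [0,1]) visible data."""
    data = np.asarray(data, dtype=float)
    params = init_rbm(data.shape[1], n_hidden, rng, config.init_sigma)
    # visible bias at the logit of the data marginals keeps early hidden
    # activations unsaturated (standard practical initialization)
    marg = np.clip(data.mean(axis=0), 1e-3, 1 - 1e-3)
    params = replace(params, b=np.log(marg / (1 - marg)))
    vel = {f: np.zeros_like(getattr(params, f)) for f in ("W", "b", "c")}
    for epoch in range(config.epochs):
        mom = (
            config.momentum_initial
            if epoch < config.momentum_switch_epoch
            else config.momentum_final
        )
        order = rng.permutation(data.shape[0])
        for start in range(0, data.shape[0], config.batch_size):
            batch = data[order[start : start + config.batch_size]]
            new = cd_update(
                params,
                batch,
                config.learning_rate,
                rng,
                k_steps=config.k_steps,
                weight_decay=config.weight_decay,
            )
            for f in ("W", "b", "c"):
                vel[f] = mom * vel[f] + (getattr(new, f) - getattr(params, f))
            params = RbmParameters(
                W=params.W + vel["W"], b=params.b + vel["b"], c=params.c + vel["c"]
            )
    return params


def train_rsm(
    counts: np.ndarray,
    n_hidden: int,
    config: CdConfig,
    rng: np.random.Generator,
) -> RsmParameters:
    """Train a replicated softmax on a matrix of word-count vectors."""
    counts = np.asarray(counts, dtype=float)
    params = init_rsm(counts.shape[1], n_hidden, rng, config.init_sigma)
    # word bias at the log of the empirical word frequencies, the standard
    # replicated-softmax initialization; keeps W from encoding frequency
    freq = counts.sum(axis=0) / max(counts.sum(), 1.0)
    params = replace(params, b=np.log(freq + 1e-8))
    vel = {f: np.zeros_like(getattr(params, f)) for f in ("W", "b", "c")}
    for epoch in range(config.epochs):
        mom = (
            config.momentum_initial
            if epoch < config.momentum_switch_epoch
            else config.momentum_final
        )
        order = rng.permutation(counts.shape[0])
        for start in range(0, counts.shape[0], config.batch_size):
            batch = counts[order[start : start + config.batch_size]]
            new = rsm_cd_update(
                params,
                batch,
                config.learning_rate,
                rng,
                k_steps=config.k_steps,
                weight_decay=config.weight_decay,
            )
            for f in ("W", "b", "c"):
                vel[f] = mom * vel[f] + (getattr(new, f) - getattr(params, f))
            params = RsmParameters(
                W=params.W + vel["W"], b=params.b + vel["b"], c=params.c + vel["c"]
            )
    return params


def reconstruction_cross_entropy(data: np.ndarray, params: RbmParameters) -> float:
    """Mean Bernoulli cross-entropy of the one-step mean-field reconstruction."""
    v = np.atleast_2d(np.asarray(data, dtype=float))
    recon = conditional_visible(conditional_hidden(v, params), params)
    eps = 1e-12
    ce = -(v * np.log(recon + eps) + (1 - v) * np.log(1 - recon + eps))
    return float(ce.mean())
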