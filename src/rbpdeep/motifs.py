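"""Generating binding motifs from the trained generative model.

The label-augmented top RBM models the joint distribution of the deep
representation and the bound/unbound label.  Clamping the label unit to 1
and running mean-field Gibbs updates in the top RBM to a fixed point,
then propagating the converged activations downward through each layer's
conditional means (ancestral down-pass), yields the expected sequence,
structure-context and tertiary profiles of bound sites; clamping to 0
yields the unbound background.  The difference

    dP = P(1D, 2D, 3D | label=1) - P(1D, 2D, 3D | label=0)

scores each RNA word and catalog motif for binding specificity.  Words
with dP above a threshold (default: the 95th percentile of the modality's
dP values) are kept, aligned into a position-frequency matrix for the
sequence modality, and the top tertiary motifs are ranked by dP.

The fixed-point mean-field iteration (rather than stochastic Gibbs
traces) makes the whole procedure deterministic and reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dbn import MultimodalDbnModel
from .encoding import PRIMARY_ALPHABET, RnaDictionary
from .io import MotifCatalog
from .rbm import conditional_hidden, conditional_visible, expit, rsm_conditional_words


@dataclass
class ExpectedProfiles:
    """Expected modality profiles generated with the label unit clamped."""

    words_1d: np.ndarray | None  # distribution over the 1D dictionary
    words_2d: np.ndarray | None  # distribution over the 2D dictionary
    tertiary: np.ndarray | None  # per-motif activation probabilities
    label: int
    steps_run: int
    converged: bool


@dataclass
class DeltaProfile:
    """Per-word / per-motif differences between bound and unbound profiles."""

    delta_1d: np.ndarray | None
    delta_2d: np.ndarray | None
    delta_3d: np.ndarray | None
    dictionary_1d: RnaDictionary | None
    dictionary_2d: RnaDictionary | None
    catalog: MotifCatalog | None


@dataclass
class MotifReport:
    """Accepted words, sequence PFM and ranked tertiary motifs."""

    words_1d: list[tuple[str, float]]
    pfm: np.ndarray | None
    words_2d: list[tuple[str, float]]
    tertiary: list[tuple[str, float]]
    steps_run: int
    converged: bool
    seed: int


def clamped_expectations(
    model: MultimodalDbnModel,
    label: int,
    steps: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
) -> ExpectedProfiles:
    """Mean-field Gibbs fixed point of the top RBM with the label clamped,
    propagated downward into expected modality profiles.

    Visible activations of the top RBM start at 0.5 and alternate with the
    hidden layer until the largest absolute change drops below ``tol`` or
    ``steps`` is exhausted; the converged activations descend through each
    lower RBM's conditional means, and the wing word distributions are read
    from the replicated-softmax softmax conditional.
    """
    if model.label_rbm is None:
        raise ValueError(
            "model lacks a label-augmented top RBM; fit_classifier with "
            "mode='generative_label_rbm' first"
        )
    if label not in (0, 1):
        raise ValueError("label must be 0 or 1")
    rbm = model.label_rbm
    p = rbm.m - 1  # non-label visible units
    v = np.full(p, 0.5)
    converged = False
    steps_run = 0
    for step in range(steps):
        full_v = np.concatenate([v, [float(label)]])
        h = conditional_hidden(full_v, rbm)
        v_new = expit(h @ rbm.W[:p].T + rbm.b[:p])
        steps_run = step + 1
        if np.max(np.abs(v_new - v)) < tol:
            v = v_new
            converged = True
            break
        v = v_new
    # ancestral down-pass through the remaining upper RBMs (conditional means)
    act = v
    for lower in reversed(model.uppers[:-1]):
        act = conditional_visible(act, lower)
    arch = model.architecture
    pos = 0
    words_1d = words_2d = tertiary = None
    if "1d" in arch.modalities:
        h_wing = act[pos : pos + arch.topics_1d]
        pos += arch.topics_1d
        words_1d = rsm_conditional_words(h_wing, model.wing_1d)
    if "2d" in arch.modalities:
        h_wing = act[pos : pos + arch.topics_2d]
        pos += arch.topics_2d
        words_2d = rsm_conditional_words(h_wing, model.wing_2d)
    if "3d" in arch.modalities:
        tertiary = act[pos : pos + arch.tertiary_dim]
    return ExpectedProfiles(
        words_1d=words_1d,
        words_2d=words_2d,
        tertiary=tertiary,
        label=label,
        steps_run=steps_run,
        converged=converged,
    )


def delta_profiles(
    p1: ExpectedProfiles,
    p0: ExpectedProfiles,
    model: MultimodalDbnModel,
) -> DeltaProfile:
    """Elementwise dP = P(.|label=1) - P(.|label=0) per modality."""

    def diff(a, b):
        if (a is None) != (b is None):
            raise ValueError("profiles come from models with different modalities")
        if a is None:
            return None
        if a.shape != b.shape:
            raise ValueError("profile dimensions disagree (mismatched dictionaries?)")
        return a - b

    return DeltaProfile(
        delta_1d=diff(p1.words_1d, p0.words_1d),
        delta_2d=diff(p1.words_2d, p0.words_2d),
        delta_3d=diff(p1.tertiary, p0.tertiary),
        dictionary_1d=model.dictionary_1d,
        dictionary_2d=model.dictionary_2d,
        catalog=model.catalog,
    )


def _resolve_threshold(values: np.ndarray, threshold, quantile) -> float:
    if threshold is not None:
        return float(threshold)
    return float(np.quantile(values, quantile))


def select_words(
    delta: DeltaProfile,
    threshold: float | None = None,
    quantile: float = 0.95,
) -> dict[str, list[tuple[str, float]]]:
    """Words with dP strictly above the threshold, per modality.

    With no explicit ``threshold`` the cut is the given quantile of the
    modality's own dP distribution.  Results are sorted by descending dP.
    """
    out: dict[str, list[tuple[str, float]]] = {}
    pairs = [
        ("1d", delta.delta_1d, None if delta.dictionary_1d is None else delta.dictionary_1d.words),
        ("2d", delta.delta_2d, None if delta.dictionary_2d is None else delta.dictionary_2d.words),
    ]
    for name, values, words in pairs:
        if values is None:
            continue
        cut = _resolve_threshold(values, threshold, quantile)
        keep = [(words[i], float(values[i])) for i in np.flatnonzero(values > cut)]
        keep.sort(key=lambda t: -t[1])
        out[name] = keep
    return out


def build_pfm(accepted: list[tuple[str, float]], alphabet: str = PRIMARY_ALPHABET) -> np.ndarray:
    """Greedy seed-and-extend alignment of accepted words into a PFM.

    The highest-dP word seeds the alignment at offset 0; each remaining
    word (in descending dP order) is placed at the integer offset within
    +-(k-1) of the current span that maximizes its dP-weighted agreement
    with the running weighted consensus.  The PFM is the dP-weighted base
    frequency per column, columns normalized to sum to 1.

    This alignment scheme is this package's own construction; nonpositive
    dP weights are floored at a small epsilon so every accepted word
    contributes.
    """
    if not accepted:
        raise ValueError("empty acceptance set; lower the dP threshold")
    eps = 1e-9
    idx = {ch: i for i, ch in enumerate(alphabet)}
    ordered = sorted(accepted, key=lambda t: -t[1])
    k = len(ordered[0][0])
    if any(len(w) != k for w, _ in ordered):
        raise ValueError("accepted words must share one length")
    span = 3 * k - 2  # offsets in [-(k-1), k-1] relative to the seed
    counts = np.zeros((span, len(alphabet)))
    origin = k - 1

    def place(word: str, weight: float, offset: int) -> None:
        for i, ch in enumerate(word):
            counts[origin + offset + i, idx[ch]] += weight

    def score(word: str, offset: int) -> float:
        total = counts.sum(axis=1)
        s = 0.0
        for i, ch in enumerate(word):
            col = origin + offset + i
            if total[col] > 0:
                s += counts[col, idx[ch]] / total[col]
        return s

    place(ordered[0][0], max(ordered[0][1], eps), 0)
    for word, weight in ordered[1:]:
        offsets = range(-(k - 1), k)
        best = max(offsets, key=lambda off: (score(word, off), -abs(off)))
        place(word, max(weight, eps), best)
    used = counts.sum(axis=1) > 0
    pfm = counts[used]
    return pfm / pfm.sum(axis=1, keepdims=True)


def rank_tertiary(delta: DeltaProfile, top_n: int = 5) -> list[tuple[str, float]]:
    """Top catalog motifs by descending dP; ties broken by catalog order."""
    if delta.delta_3d is None or delta.catalog is None:
        raise ValueError("tertiary modality inactive in this model")
    ids = delta.catalog.hairpin_ids + delta.catalog.internal_ids
    if top_n > len(ids):
        warnings.warn(
            f"top_n={top_n} exceeds catalog size {len(ids)}; returning full ranking"
        )
        top_n = len(ids)
    order = np.argsort(-delta.delta_3d, kind="stable")[:top_n]
    return [(ids[i], float(delta.delta_3d[i])) for i in order]


def generate_motif_report(
    model: MultimodalDbnModel,
    steps: int = 500,
    tol: float = 1e-6,
    threshold: float | None = None,
    quantile: float = 0.95,
    top_n_tertiary: int = 5,
    seed: int = 0,
) -> MotifReport:
    """End-to-end motif generation from a model with a label RBM."""
    p1 = clamped_expectations(model, 1, steps=steps, tol=tol, seed=seed)
    p0 = clamped_expectations(model, 0, steps=steps, tol=tol, seed=seed)
    delta = delta_profiles(p1, p0, model)
    accepted = select_words(delta, threshold=threshold, quantile=quantile)
    words_1d = accepted.get("1d", [])
    pfm = build_pfm(words_1d) if words_1d else None
    tert = rank_tertiary(delta, top_n_tertiary) if delta.delta_3d is not None else []
    return MotifReport(
        words_1d=words_1d,
        pfm=pfm,
        words_2d=accepted.get("2d", []),
        tertiary=tert,
        steps_run=max(p1.steps_run, p0.steps_run),
        converged=p1.converged and p0.converged,
        seed=seed,
    )
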