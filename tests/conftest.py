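"""Shared fixtures: small synthetic datasets, toy model configs, and the
seeded benchmark harness used by the end-to-end tests."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import rbpdeep as rd
from rbpdeep.encoding import (
    annotate_contexts,
    build_dictionary,
    encode_dataset,
    full_dictionary,
)
from rbpdeep.rbm import CdConfig

TOY_ARCH = rd.ArchitectureSpec(
    topics_1d=50, topics_2d=30, tertiary_dim=16, upper_layers=(64, 64)
)
TOY_CD = CdConfig(epochs=80)
#: the structure-context word implanted by the generator's hairpin bias:
#: a 12-nt hairpin loop yields runs of H longer than the 2D word length
CONTEXT_WORD = "HHHHHHHH"


def random_balanced_dot_bracket(rng: np.random.Generator, length: int) -> str:
    """Random balanced dot-bracket of exactly ``length`` characters."""
    out: list[str] = []
    open_count = 0
    for pos in range(length):
        remaining = length - pos
        if remaining == open_count:  # must close everything that is open
            out.append(")")
            open_count -= 1
            continue
        r = rng.random()
        if r < 0.3 and remaining > open_count + 1:
            out.append("(")
            open_count += 1
        elif r < 0.55 and open_count > 0:
            out.append(")")
            open_count -= 1
        else:
            out.append(".")
    return "".join(out)


def encode_pair(train, test, k1: int = 6):
    """Encode train/test datasets with dictionaries built on train."""
    d1 = full_dictionary("primary", k1)
    docs2 = [annotate_contexts(s.dot_bracket) for s in train.structures]
    d2 = build_dictionary(docs2, "secondary", 8, mode="observed_words")
    enc_tr = encode_dataset(
        train.sites, train.structures, train.loop_scores, d1, d2, train.catalog
    )
    enc_te = encode_dataset(
        test.sites, test.structures, test.loop_scores, d1, d2, test.catalog
    )
    return enc_tr, enc_te


def run_benchmark_seed(seed: int) -> dict:
    """One seed of the synthetic recovery benchmark: train on the default
    generator (500/500), test on a fresh 200/200 draw, measure AUROC of the
    full and tertiary-ablated models and the dP ranks of the three
    implanted signals."""
    cfg = rd.SyntheticConfig(seed=seed)
    train = rd.generate_dataset(cfg)
    test = rd.generate_dataset(
        dataclasses.replace(cfg, n_pos=200, n_neg=200, seed=seed + 1000)
    )
    enc_tr, enc_te = encode_pair(train, test)

    model = rd.pretrain(enc_tr, TOY_ARCH, TOY_CD, seed=seed)
    model = rd.fit_classifier(model, enc_tr, train.labels, mode="discriminative_head")
    auroc_full = rd.auroc(rd.predict(model, enc_te), test.labels)

    arch_ablated = dataclasses.replace(TOY_ARCH, modalities=("1d", "2d"))
    ablated = rd.pretrain(enc_tr, arch_ablated, TOY_CD, seed=seed)
    ablated = rd.fit_classifier(ablated, enc_tr, train.labels, mode="discriminative_head")
    auroc_ablated = rd.auroc(rd.predict(ablated, enc_te), test.labels)

    model = rd.fit_classifier(
        model, enc_tr, train.labels, mode="generative_label_rbm", config=TOY_CD, seed=seed
    )
    from rbpdeep.motifs import clamped_expectations, delta_profiles

    p1 = clamped_expectations(model, 1)
    p0 = clamped_expectations(model, 0)
    delta = delta_profiles(p1, p0, model)
    words_1d = model.dictionary_1d.words
    rank_1d = int(
        list(np.argsort(-delta.delta_1d)).index(words_1d.index(cfg.implant_motif))
    )
    words_2d = model.dictionary_2d.words
    if CONTEXT_WORD in words_2d:
        rank_2d = int(
            list(np.argsort(-delta.delta_2d)).index(words_2d.index(CONTEXT_WORD))
        )
    else:
        rank_2d = len(words_2d)
    order_3d = list(np.argsort(-delta.delta_3d))
    rank_3d = min(order_3d.index(b) for b in cfg.informative_bits)
    return {
        "auroc_full": auroc_full,
        "auroc_ablated": auroc_ablated,
        "drop": auroc_full - auroc_ablated,
        "rank_1d": rank_1d,
        "rank_2d": rank_2d,
        "rank_3d": rank_3d,
    }


@pytest.fixture(scope="session")
def tiny_dataset():
    """60/60 default-signal sites with toy catalog, for unit-level tests."""
    cfg = rd.SyntheticConfig(n_pos=60, n_neg=60, seed=11)
    return rd.generate_dataset(cfg)


@pytest.fixture(scope="session")
def tiny_encoded(tiny_dataset):
    d1 = full_dictionary("primary", 2)
    docs2 = [annotate_contexts(s.dot_bracket) for s in tiny_dataset.structures]
    d2 = build_dictionary(docs2, "secondary", 3, mode="observed_words")
    return encode_dataset(
        tiny_dataset.sites,
        tiny_dataset.structures,
        tiny_dataset.loop_scores,
        d1,
        d2,
        tiny_dataset.catalog,
    )


@pytest.fixture(scope="session")
def tiny_model(tiny_dataset, tiny_encoded):
    arch = rd.ArchitectureSpec(
        topics_1d=8, topics_2d=6, tertiary_dim=16, upper_layers=(16, 16)
    )
    cd = CdConfig(epochs=15)
    model = rd.pretrain(tiny_encoded, arch, cd, seed=5)
    model = rd.fit_classifier(
        model, tiny_encoded, tiny_dataset.labels, mode="discriminative_head"
    )
    model = rd.fit_classifier(
        model, tiny_encoded, tiny_dataset.labels,
        mode="generative_label_rbm", config=cd, seed=5,
    )
    return model
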