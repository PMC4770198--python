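"""Multimodal deep belief network: two replicated-softmax wings (sequence
k-mers, structure-context k-mers) joined with the tertiary motif bits in a
hybrid layer, topped by a stack of binary RBMs.

The published full-scale architecture is (d1, d2) - (2000, 1000, 529) -
3000 - 3000: d1/d2-dimensional count vectors feed wings with 2000 and 1000
latent topics, the wing activations are concatenated with the 529 motif
indicator bits, and two 3000-unit RBM layers sit on top.  Scale is pure
configuration here; tests and examples run reduced architectures.

Training is greedy and layer-wise: each wing is trained as a replicated
softmax on its count vectors, then each upper RBM on the mean-field
activations of the layer below (activations are passed upward as
probabilities, the standard low-variance choice for greedy pretraining).
Two prediction heads are provided: a discriminative logistic head on the
top-layer representation (default), and a generative head that retrains
the top RBM with a label unit appended to its visible layer and scores a
site by the free-energy difference F(x, label=0) - F(x, label=1).  The
label-augmented top RBM is also what the motif generator samples from.
"""

from __future__ import annotations

import hashlib

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression

from .encoding import EncodedDataset, RnaDictionary
from .io import MotifCatalog
from .rbm import (
    CdConfig,
    RbmParameters,
    RsmParameters,
    conditional_hidden,
    free_energy,
    rsm_conditional_hidden,
    train_rbm,
    train_rsm,
)

MODALITIES = ("1d", "2d", "3d")


@dataclass(frozen=True)
class ArchitectureSpec:
    """Layer sizes and the active-modality mask of a multimodal DBN.

    Defaults are the full published scale; pass smaller numbers for toy
    models.  ``tertiary_dim`` must match the motif catalog size when the
    3D modality is active.
    """

    topics_1d: int = 2000
    topics_2d: int = 1000
    tertiary_dim: int = 529
    upper_layers: tuple[int, ...] = (3000, 3000)
    modalities: tuple[str, ...] = MODALITIES

    def __post_init__(self) -> None:
        if not self.modalities:
            raise ValueError("at least one modality must be active")
        bad = set(self.modalities) - set(MODALITIES)
        if bad:
            raise ValueError(f"unknown modalities {sorted(bad)}")
        if not self.upper_layers:
            raise ValueError("need at least one upper RBM layer")
        dims = (self.topics_1d, self.topics_2d, self.tertiary_dim) + tuple(self.upper_layers)
        if any(d < 1 for d in dims):
            raise ValueError("all layer dimensions must be >= 1")

    @property
    def hybrid_dim(self) -> int:
        dim = 0
        if "1d" in self.modalities:
            dim += self.topics_1d
        if "2d" in self.modalities:
            dim += self.topics_2d
        if "3d" in self.modalities:
            dim += self.tertiary_dim
        return dim


def _fingerprint(words: tuple[str, ...]) -> str:
    return hashlib.sha256("\n".join(words).encode()).hexdigest()[:16]


@dataclass
class MultimodalDbnModel:
    """Trained stack plus the dictionaries/catalog it was encoded with."""

    architecture: ArchitectureSpec
    wing_1d: RsmParameters | None
    wing_2d: RsmParameters | None
    uppers: list[RbmParameters]
    dictionary_1d: RnaDictionary | None
    dictionary_2d: RnaDictionary | None
    catalog: MotifCatalog | None
    seed: int
    head_coef: np.ndarray | None = None  # logistic head on top layer
    head_intercept: float | None = None
    label_rbm: RbmParameters | None = None  # top RBM with label unit appended

    # -- up-pass ----------------------------------------------------------

    def _check_profiles(self, profiles: EncodedDataset) -> None:
        arch = self.architecture
        if "1d" in arch.modalities:
            if self.dictionary_1d is None or _fingerprint(
                profiles.dictionary_1d.words
            ) != _fingerprint(self.dictionary_1d.words):
                raise ValueError(
                    "1D dictionary of the profiles does not match the model's; "
                    "re-encode the sites with the model's own dictionaries"
                )
        if "2d" in arch.modalities:
            if self.dictionary_2d is None or _fingerprint(
                profiles.dictionary_2d.words
            ) != _fingerprint(self.dictionary_2d.words):
                raise ValueError(
                    "2D dictionary of the profiles does not match the model's"
                )
        if "3d" in arch.modalities:
            model_ids = self.catalog.hairpin_ids + self.catalog.internal_ids
            prof_ids = profiles.catalog.hairpin_ids + profiles.catalog.internal_ids
            if model_ids != prof_ids:
                raise ValueError("motif catalog of the profiles does not match the model's")

    def hybrid_layer(self, profiles: EncodedDataset) -> np.ndarray:
        """Concatenate wing hidden probabilities and tertiary bits."""
        self._check_profiles(profiles)
        parts = []
        if "1d" in self.architecture.modalities:
            parts.append(rsm_conditional_hidden(profiles.counts_1d.astype(float), self.wing_1d))
        if "2d" in self.architecture.modalities:
            parts.append(rsm_conditional_hidden(profiles.counts_2d.astype(float), self.wing_2d))
        if "3d" in self.architecture.modalities:
            parts.append(profiles.bits_3d.astype(float))
        return np.concatenate(parts, axis=1)

    def penultimate(self, profiles: EncodedDataset) -> np.ndarray:
        """Mean-field activations just below the top RBM."""
        act = self.hybrid_layer(profiles)
        for rbm in self.uppers[:-1]:
            act = conditional_hidden(act, rbm)
        return act

    def joint_representation(self, profiles: EncodedDataset) -> np.ndarray:
        """Deterministic mean-field up-pass to the top layer, in [0, 1]."""
        act = self.hybrid_layer(profiles)
        for rbm in self.uppers:
            act = conditional_hidden(act, rbm)
        return act

    # -- serialization ----------------------------------------------------

    def to_arrays(self) -> tuple[dict, dict]:
        arrays: dict[str, np.ndarray] = {}
        for name, wing in (("wing_1d", self.wing_1d), ("wing_2d", self.wing_2d)):
            if wing is not None:
                arrays[f"{name}_W"] = wing.W
                arrays[f"{name}_b"] = wing.b
                arrays[f"{name}_c"] = wing.c
        for i, rbm in enumerate(self.uppers):
            arrays[f"upper{i}_W"] = rbm.W
            arrays[f"upper{i}_b"] = rbm.b
            arrays[f"upper{i}_c"] = rbm.c
        if self.head_coef is not None:
            arrays["head_coef"] = self.head_coef
            arrays["head_intercept"] = np.array([self.head_intercept])
        if self.label_rbm is not None:
            arrays["label_rbm_W"] = self.label_rbm.W
            arrays["label_rbm_b"] = self.label_rbm.b
            arrays["label_rbm_c"] = self.label_rbm.c
        meta = {
            "architecture": {
                "topics_1d": self.architecture.topics_1d,
                "topics_2d": self.architecture.topics_2d,
                "tertiary_dim": self.architecture.tertiary_dim,
                "upper_layers": list(self.architecture.upper_layers),
                "modalities": list(self.architecture.modalities),
            },
            "n_uppers": len(self.uppers),
            "seed": self.seed,
            "dictionary_1d": None
            if self.dictionary_1d is None
            else {"k": self.dictionary_1d.k, "words": list(self.dictionary_1d.words)},
            "dictionary_2d": None
            if self.dictionary_2d is None
            else {"k": self.dictionary_2d.k, "words": list(self.dictionary_2d.words)},
            "catalog": None
            if self.catalog is None
            else {
                "hairpin_ids": list(self.catalog.hairpin_ids),
                "internal_ids": list(self.catalog.internal_ids),
                "version": self.catalog.version,
            },
        }
        return arrays, meta

    @classmethod
    def from_arrays(cls, arrays: dict, meta: dict) -> "MultimodalDbnModel":
        arch = ArchitectureSpec(
            topics_1d=meta["architecture"]["topics_1d"],
            topics_2d=meta["architecture"]["topics_2d"],
            tertiary_dim=meta["architecture"]["tertiary_dim"],
            upper_layers=tuple(meta["architecture"]["upper_layers"]),
            modalities=tuple(meta["architecture"]["modalities"]),
        )

        def wing(name):
            if f"{name}_W" not in arrays:
                return None
            return RsmParameters(
                W=arrays[f"{name}_W"], b=arrays[f"{name}_b"], c=arrays[f"{name}_c"]
            )

        uppers = [
            RbmParameters(
                W=arrays[f"upper{i}_W"], b=arrays[f"upper{i}_b"], c=arrays[f"upper{i}_c"]
            )
            for i in range(meta["n_uppers"])
        ]
        d1 = meta["dictionary_1d"]
        d2 = meta["dictionary_2d"]
        cat = meta["catalog"]
        return cls(
            architecture=arch,
            wing_1d=wing("wing_1d"),
            wing_2d=wing("wing_2d"),
            uppers=uppers,
            dictionary_1d=None
            if d1 is None
            else RnaDictionary("primary", d1["k"], tuple(d1["words"])),
            dictionary_2d=None
            if d2 is None
            else RnaDictionary("secondary", d2["k"], tuple(d2["words"])),
            catalog=None
            if cat is None
            else MotifCatalog(
                tuple(cat["hairpin_ids"]), tuple(cat["internal_ids"]), cat["version"]
            ),
            seed=meta["seed"],
            head_coef=arrays.get("head_coef"),
            head_intercept=float(arrays["head_intercept"][0])
            if "head_intercept" in arrays
            else None,
            label_rbm=RbmParameters(
                W=arrays["label_rbm_W"], b=arrays["label_rbm_b"], c=arrays["label_rbm_c"]
            )
            if "label_rbm_W" in arrays
            else None,
        )


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def pretrain(
    profiles: EncodedDataset,
    architecture: ArchitectureSpec,
    config: CdConfig | None = None,
    seed: int = 0,
) -> MultimodalDbnModel:
    """Greedy layer-wise pretraining of the full stack (no labels used).

    Each wing is trained as a replicated softmax on its count vectors;
    upper RBMs are trained on the mean-field activations of the layer
    below.  Fully deterministic given ``(profiles, architecture, config,
    seed)``.
    """
    if profiles.n_sites == 0:
        raise ValueError("empty dataset")
    config = config or CdConfig()
    arch = architecture
    if "3d" in arch.modalities and profiles.catalog.size != arch.tertiary_dim:
        raise ValueError(
            f"architecture tertiary_dim={arch.tertiary_dim} but catalog has "
            f"{profiles.catalog.size} motifs"
        )
    rng = np.random.default_rng(seed)
    wing_1d = wing_2d = None
    parts = []
    if "1d" in arch.modalities:
        x1 = profiles.counts_1d.astype(float)
        wing_1d = train_rsm(x1, arch.topics_1d, config, rng)
        parts.append(rsm_conditional_hidden(x1, wing_1d))
    if "2d" in arch.modalities:
        x2 = profiles.counts_2d.astype(float)
        wing_2d = train_rsm(x2, arch.topics_2d, config, rng)
        parts.append(rsm_conditional_hidden(x2, wing_2d))
    if "3d" in arch.modalities:
        parts.append(profiles.bits_3d.astype(float))
    act = np.concatenate(parts, axis=1)
    uppers = []
    for size in arch.upper_layers:
        rbm = train_rbm(act, size, config, rng)
        uppers.append(rbm)
        act = conditional_hidden(act, rbm)
    return MultimodalDbnModel(
        architecture=arch,
        wing_1d=wing_1d,
        wing_2d=wing_2d,
        uppers=uppers,
        dictionary_1d=profiles.dictionary_1d if "1d" in arch.modalities else None,
        dictionary_2d=profiles.dictionary_2d if "2d" in arch.modalities else None,
        catalog=profiles.catalog if "3d" in arch.modalities else None,
        seed=seed,
    )


def fit_classifier(
    model: MultimodalDbnModel,
    profiles: EncodedDataset,
    labels: np.ndarray,
    mode: str = "discriminative_head",
    config: CdConfig | None = None,
    seed: int = 0,
) -> MultimodalDbnModel:
    """Attach a prediction head to a pretrained model.

    ``discriminative_head`` fits a logistic classifier on the top-layer
    representations.  ``generative_label_rbm`` retrains the top RBM with a
    label unit appended to its visible layer; prediction then uses the
    free-energy difference between the label-off and label-on completions.
    Either way the lower layers stay fixed.
    """
    labels = np.asarray(labels, dtype=int)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("need both bound (1) and unbound (0) labels")
    if mode == "discriminative_head":
        rep = model.joint_representation(profiles)
        clf = LogisticRegression(max_iter=2000, C=1.0)
        clf.fit(rep, labels)
        model.head_coef = clf.coef_[0].copy()
        model.head_intercept = float(clf.intercept_[0])
        return model
    if mode == "generative_label_rbm":
        config = config or CdConfig()
        rng = np.random.default_rng(seed + 1)
        penult = model.penultimate(profiles)
        visible = np.concatenate([penult, labels[:, None].astype(float)], axis=1)
        model.label_rbm = train_rbm(
            visible, model.architecture.upper_layers[-1], config, rng
        )
        return model
    raise ValueError(f"unknown mode {mode!r}")


def label_free_energy_scores(
    model: MultimodalDbnModel, profiles: EncodedDataset
) -> np.ndarray:
    """F(x, label=0) - F(x, label=1) under the label-augmented top RBM."""
    if model.label_rbm is None:
        raise ValueError("model has no generative label RBM; run fit_classifier")
    penult = model.penultimate(profiles)
    v0 = np.concatenate([penult, np.zeros((penult.shape[0], 1))], axis=1)
    v1 = np.concatenate([penult, np.ones((penult.shape[0], 1))], axis=1)
    return np.atleast_1d(free_energy(v0, model.label_rbm)) - np.atleast_1d(
        free_energy(v1, model.label_rbm)
    )


def predict(model: MultimodalDbnModel, profiles: EncodedDataset) -> np.ndarray:
    """Per-site binding score in [0, 1]; higher means more likely bound.

    Uses the discriminative head when fitted, otherwise the generative
    label RBM (logistic of the free-energy difference).
    """
    if model.head_coef is not None:
        rep = model.joint_representation(profiles)
        z = rep @ model.head_coef + model.head_intercept
        return 1.0 / (1.0 + np.exp(-z))
    if model.label_rbm is not None:
        from scipy.special import expit

        return expit(label_free_energy_scores(model, profiles))
    raise ValueError("model has no fitted prediction head")
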