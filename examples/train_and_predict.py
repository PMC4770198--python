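"""Train a toy multimodal DBN on synthetic sites and score a held-out set.

Also trains a tertiary-ablated model (sequence + secondary structure
only) to show the AUROC cost of dropping the 3D modality when the data
carry tertiary signal — the same comparison used to flag structure-
dependent RBPs on real CLIP-seq benchmarks.
"""

import dataclasses

import rbpdeep as rd
from rbpdeep.encoding import annotate_contexts, build_dictionary, encode_dataset, full_dictionary
from rbpdeep.rbm import CdConfig

config = rd.SyntheticConfig(n_pos=300, n_neg=300, seed=7)
train = rd.generate_dataset(config)
test = rd.generate_dataset(dataclasses.replace(config, n_pos=150, n_neg=150, seed=1007))

dict_1d = full_dictionary("primary", 6)
context_docs = [annotate_contexts(s.dot_bracket) for s in train.structures]
dict_2d = build_dictionary(context_docs, "secondary", 8, mode="observed_words")
enc_train = encode_dataset(
    train.sites, train.structures, train.loop_scores, dict_1d, dict_2d, train.catalog
)
enc_test = encode_dataset(
    test.sites, test.structures, test.loop_scores, dict_1d, dict_2d, test.catalog
)

# reduced architecture: 50 + 30 topics + 16 motif bits -> 64 -> 64
arch = rd.ArchitectureSpec(topics_1d=50, topics_2d=30, tertiary_dim=16, upper_layers=(64, 64))
cd = CdConfig(epochs=80)

model = rd.pretrain(enc_train, arch, cd, seed=7)
model = rd.fit_classifier(model, enc_train, train.labels, mode="discriminative_head")
auroc_full = rd.auroc(rd.predict(model, enc_test), test.labels)

ablated_arch = dataclasses.replace(arch, modalities=("1d", "2d"))
ablated = rd.pretrain(enc_train, ablated_arch, cd, seed=7)
ablated = rd.fit_classifier(ablated, enc_train, train.labels, mode="discriminative_head")
auroc_ablated = rd.auroc(rd.predict(ablated, enc_test), test.labels)

print(f"held-out AUROC, full model (1D+2D+3D): {auroc_full:.3f}")
print(f"held-out AUROC, tertiary-ablated (1D+2D): {auroc_ablated:.3f}")
print(f"AUROC cost of removing tertiary profiles: {auroc_full - auroc_ablated:.3f}")
print(
    "a drop above 0.02 marks the dataset as tertiary-structure-dependent "
    "(here the generator implants two informative catalog motifs)"
)
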