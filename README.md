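# rbpdeep

Multimodal deep belief networks for modeling the target preferences of
RNA-binding proteins (RBPs) from CLIP-seq-style binding-site data.

RBPs recognize their RNA targets through primary sequence and through
secondary and tertiary structure. `rbpdeep` encodes each candidate site
into three modality profiles and integrates them in one generative model:

* **1D** — counts of 6-mers overlapping the *viewpoint* (the bound
  interval) of the site, a bag-of-words document over the 4096-word RNA
  dictionary;
* **2D** — counts of 8-mers over the S/M/H/I/B/E structure-context
  strings (stem, multiloop, hairpin loop, internal loop, bulge, external)
  of the site's predicted secondary-structure ensemble;
* **3D** — a binary *motif indicating vector* marking which catalog
  tertiary motifs (hairpin / internal loop modules, scored JAR3D-style)
  the viewpoint loops can form.

Each count modality feeds a replicated softmax — an RBM over word counts
with energy `E(V,h) = −h'W'v̂ − b'v̂ − D·c'h` — whose latent "topic"
activations are concatenated with the tertiary bits and topped by a stack
of binary RBMs (`E(v,h) = −v'Wh − b'v − c'h`), pretrained greedily with
contrastive divergence. The trained stack predicts binding sites (logistic
head or label-RBM free-energy difference) and, run generatively with the
label unit clamped, produces sequence, structure-context and tertiary
binding motifs ranked by

    dP = P(1D, 2D, 3D | label=1) − P(1D, 2D, 3D | label=0).

The documented full-scale architecture is
`(d1, d2) – (2000, 1000, 529) – 3000 – 3000`; every size is configuration,
and the bundled tests and examples run a reduced stack.

## Worked example

`examples/` holds one short script per capability. Training a reduced
model on the synthetic benchmark and ablating the tertiary modality
(`python examples/train_and_predict.py`):

```
held-out AUROC, full model (1D+2D+3D): 0.993
held-out AUROC, tertiary-ablated (1D+2D): 0.963
AUROC cost of removing tertiary profiles: 0.030
```

The synthetic generator implants a 6-mer (UCUUCU) in bound viewpoints,
biases bound-site structures toward viewpoint-centered hairpin loops and
activates two informative tertiary catalog motifs, so the full model
outperforms the ablated one exactly when the pipeline exploits the 3D
bits. Generating motifs from the same model
(`python examples/generate_motifs.py`):

```
top sequence 6-mers by dP (implanted motif was UCUUCU):
  UCUUCU  dP=+0.0255
  CUUCUU  dP=+0.0071
  ...
top structure-context 8-mers by dP (generator favors hairpin loops):
  HHHHHHHH  dP=+0.0792
top 5 tertiary catalog motifs by dP (informative bits were ['HL_T01', 'IL_T01']):
  HL_T01  dP=+0.94049
  IL_T01  dP=+0.86685
  ...
sequence PFM consensus after dP-weighted alignment: UUCUUCUU
```

All three planted signals surface at the top of their modality's dP
ranking, and the accepted 6-mers align into a pyrimidine-rich consensus.
`examples/benchmark_summary.py` reproduces the bundled 24-dataset
CLIP-seq comparison: 19/24 strict wins of the full model over the
GraphProt baseline, a 73% relative error reduction on PTB HITS-CLIP
(0.937 → 0.983), and exactly three datasets (ALKBH5, MOV10, PTB) losing
more than 2% AUROC without tertiary profiles.

A thin CLI mirrors the pipeline for shell use:

```bash
rbpdeep simulate --out-dir data --n-pos 200 --n-neg 200 --seed 1
rbpdeep train --fasta data/sites.fa --structures data/structures.tsv \
    --loops data/loop_scores.tsv --catalog data/catalog.tsv \
    --labels data/labels.tsv --model-out model.npz
rbpdeep predict --model model.npz --fasta data/sites.fa \
    --structures data/structures.tsv --loops data/loop_scores.tsv --out scores.tsv
rbpdeep motifs --model model.npz --out-dir motifs/
```

Inputs are plain text: viewpoint FASTA (uppercase viewpoint, lowercase
flanks), a structure TSV of dot-brackets per window, a loop-score TSV in
the style of JAR3D output, and a two-column motif catalog TSV. Models are
single self-contained `.npz` archives.

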