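# Methods

## Model

`rbpdeep` models an RNA-binding protein's target preferences as a joint
generative distribution over three views of a candidate site:

* **1D (primary sequence).** The viewpoint region — the experimentally
  identified bound interval inside a longer flanked sequence — is scanned
  with a sliding window of length `k1 = 6` and step 1. Every 6-mer window
  overlapping the viewpoint by at least one nucleotide contributes one
  count; the resulting bag-of-words count vector over the 4^6 = 4096-word
  RNA dictionary is the site's 1D document.
* **2D (secondary structure).** Each predicted secondary structure of the
  site (an ensemble of up to a few dot-bracket strings per folding
  window) is rewritten over the six-letter context alphabet S/M/H/I/B/E
  (stem, multiloop, hairpin loop, internal loop, bulge, external) by loop
  decomposition of the pair table, then scanned the same way with
  `k2 = 8`. Counts are summed over the whole ensemble (a union mode that
  takes the per-structure maximum is available instead).
* **3D (tertiary motifs).** Hairpin and internal loops (bulges count as
  one-sided internal loops) overlapping the viewpoint carry JAR3D-style
  scores against a catalog of recurrent tertiary motifs (hairpin block
  first, internal block second; the documented atlas release has
  253 + 276 = 529 entries). A score strictly above the cutoff (default 0)
  sets the motif's bit in a binary indicating vector.

Each count-vector modality feeds a **replicated softmax** — an RBM whose
K softmax visible units share tied weights across the D word slots of a
document, with energy

    E(V, h) = − h'W'v̂ − b'v̂ − D·c'h,

so all quantities depend on the document only through its count vector v̂
and the document size D. The hidden "topic" activations of the two wings
are concatenated with the tertiary bits into a hybrid layer, on top of
which a stack of ordinary binary RBMs (energy E(v,h) = −v'Wh − b'v − c'h)
is trained greedily, layer by layer, with CD-1. The documented full-scale
architecture is (d1, d2) – (2000, 1000, 529) – 3000 – 3000; all layer
sizes are configuration, and tests/examples use a reduced stack
(50, 30, 16) – 64 – 64.

## Training and prediction

Greedy pretraining passes mean-field probabilities upward (lower variance
than sampling). Two prediction heads exist:

* **discriminative (default):** logistic regression on the top-layer
  mean-field representation;
* **generative:** the top RBM is retrained with a label unit appended to
  its visible layer; a site is scored by the free-energy difference
  F(x, label=0) − F(x, label=1), whose sign equals the enumerated
  posterior criterion p(label=1 | x) > 1/2 exactly.

Contrastive-divergence defaults (CD-1, minibatch 100, learning rate 0.05,
momentum 0.5 → 0.9 after epoch 5, weight decay 2e-4, 40 epochs) follow
standard DBN practice and are fully exposed via `CdConfig`; the reduced
benchmark stack uses 80 epochs, at which the upper layers reliably carry
the hybrid-layer signal.

### Numerical choices

Three choices matter in practice and are deliberate:

* **Bias initialization.** Binary-RBM visible biases start at the logit
  of the data marginals and replicated-softmax word biases at the log of
  the empirical word frequencies. Without this, the weights must encode
  first-order statistics and the hidden layer saturates before learning
  correlations.
* **Hidden-bias preconditioning (replicated softmax).** The gradient of
  the D-scaled hidden bias carries a factor of D (~110 for the 2D wing),
  which multiplies the effective learning rate and drives the topic units
  into saturation. The update divides this gradient by the batch-mean D —
  a diagonal preconditioner that rescales the step without moving any
  stationary point.
* **Stability forms.** Free energies use softplus, partition functions
  log-sum-exp; everything is double precision. Exact enumeration oracles
  refuse instances beyond 20 binary units.

All randomness flows through a single `numpy.random.Generator` per
operation, so (data, config, seed) determines the model archive bit for
bit.

## Motif generation

The label-augmented top RBM models P(representation, label). Clamping the
label unit and iterating mean-field updates between the top RBM's layers
(initialized at 0.5, tolerance 1e-6, at most 500 steps) reaches a
deterministic fixed point approximating the clamped conditional
expectation; the converged activations descend through each lower layer's
conditional means, and the wings' softmax conditionals turn hidden means
into word distributions. The difference

    dP = P(1D, 2D, 3D | label=1) − P(1D, 2D, 3D | label=0)

ranks words and catalog motifs. Words above a threshold (default: the
95th percentile of the modality's own dP values) are kept; the accepted
sequence words are aligned into a position-frequency matrix by a greedy
seed-and-extend scheme (highest-dP word seeds; each next word takes the
offset within ±(k−1) that best matches the running weighted consensus;
columns are dP-weighted base frequencies normalized to 1). This PFM
assembly is this package's own construction — the upstream literature
displays logos without specifying one. The top tertiary motifs are the
catalog entries with the largest dP, ties broken by catalog order.

A deterministic fixed point was chosen over stochastic Gibbs traces
because reproducibility matters more here than sampling diversity; the
mean-field expectation is validated against exact clamped conditionals on
enumerable models (total variation < 0.05).

**Resolution rule.** dP values smaller than the mean-field tolerance
(1e-6) are unresolved fixed-point noise and are treated as zero signal;
the label-permutation null check applies this floor, since on null data
every max |dP| lands near 1e-9 and ranking such values compares rounding
error, not biology.

## Evaluation

AUROC uses the Mann–Whitney convention (ties 0.5). Cross-validation is
stratified (guaranteeing both classes per fold on small data, which the
upstream description leaves open), deterministic per seed, and retrains
the model per fold; modality profiles are encoded once on the full
dataset because dictionary construction is label-free. Relative error
reduction is (c′ − c)/(1 − c). The bundled 24-dataset CLIP-seq benchmark
table drives the summary functions: strict wins, per-row RER, and
flagging of rows where the full model beats its tertiary-ablated variant
by more than 0.02 AUROC ("> 2%" is read as absolute AUROC difference).
The benchmark's mean/median RER over all 24 rows depends on rounding of
the printed AUROCs and is reported but not asserted.

## Synthetic data

The generator emulates the statistical structure the framework assumes,
not CLIP-seq read-level artifacts. Defaults (fixed once, used by the
recovery benchmark): 500 bound / 500 unbound sites of 150 nt with a 30-nt
viewpoint; uniform base composition; the pyrimidine-rich 6-mer UCUUCU
implanted in bound viewpoints with probability 0.9; an ensemble of three
structures per site, rendered directly as dot-brackets (one stem-loop
with a 12-nt hairpin loop and a 2-nt bulge), centered on the viewpoint
for 70% of bound-site structures and uniformly otherwise; two informative
tertiary catalog motifs (one hairpin, one internal) active with
probability 0.9 in bound vs 0.05 in unbound sites over a 5% background
rate, plus occasional sub-threshold decoy scores that exercise the
cutoff. Unbound sites are implant-free background draws whose viewpoints
are repositioned uniformly (position shuffling), mirroring how unbound
sites derive from bound ones in the real benchmarks.

Structures are sampled layouts, not thermodynamic folds: tests need
controlled context labels, not realistic energetics. Consequently a
passing recovery benchmark shows that the pipeline can extract and
attribute planted sequence/context/tertiary signals — it does not show
that real folding ensembles or real motif catalogs are equally
informative. Sites are short (one folding window), so the 150-nt
window/37-nt step scanning logic is exercised by its own unit tests
rather than by the benchmark.

Problem sizes in the test suite (500/500 training sites, 200/200 held
out, 10 benchmark seeds, 20 null seeds, reduced architecture) were chosen
so the full suite trains dozens of models in a few minutes on a single
core while leaving comfortable statistical margins (observed: median
held-out AUROC 0.997, median tertiary-ablation drop 0.041, implanted
signals at dP rank 1 in all three modalities).

## Known limitations

* No backpropagation fine-tuning of the lower layers (the upstream
  procedure's details are not public); the greedy stack plus a head is
  what is implemented, with both head variants exposed.
* The exact 2D dictionary dimension of the original full-scale runs is
  unknown; the observed-words dictionary stands in (6^8 enumeration is
  impractical and mostly empty).
* The full-dimension tertiary catalog constructor emits synthetic
  placeholder identifiers with the documented section sizes; real atlas
  identifiers must be supplied as a catalog TSV to score real JAR3D
  output.
* Secondary-structure prediction and JAR3D scoring are out of scope: the
  package parses their outputs, it does not run them.
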