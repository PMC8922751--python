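# Methods

## Model

The classifier maps a one-hot encoded sequence window (length W,
channels A, T, C, G, N at indices 0–4) to a two-class softmax:

- convolution: F filters of width L over the 5 channels, valid padding,
  so the output length is W − L + 1;
- ReLU; non-overlapping max-pooling of width P with stride P (the last
  partial block is discarded: ⌊(W − L + 1)/P⌋ blocks);
- dropout (rate 0.5 by default) on the pooled features;
- dense layer (32 units by default) with ReLU; dense layer to 2 logits;
  softmax with cross-entropy loss.

With the 1000-nt windows and the selected initiation-stage
configuration (F = 24, L = 14, P = 10) the convolution output has
length 987 and pooling yields 98 blocks. The default hyperparameter
grid is 7 filter counts {8, 16, 24, 32, 40, 48, 64} × 6 widths
{8, 12, 14, 16, 18, 22} × 5 pool widths {5, 10, 15, 20, 25} — 210
configurations, each scored by mean fivefold-CV accuracy; ties prefer
fewer trainable parameters, then lower grid index.

Training is Adam (lr 1e-3, β = 0.9/0.999), minibatch 64, with early
stopping on validation accuracy and best-weight restoration. The
forward/backward passes are plain float32 BLAS matrix products over
materialized sliding windows, so no deep-learning framework is
involved; the backward pass is checked against finite differences in
the test suite, and the layers stay simple enough for exact attribution
(below).

Two initialization details matter. The pooled features are all
positive, and with a cold-started softmax head the fastest initial loss
decrease is to collapse the output to the class prior; empirically this
drives the entire dense ReLU layer dead and permanently cuts the
gradient path to the kernels. The output layer is therefore initialized
near zero (0.01 × He) and the hidden biases at +0.1. Dropout doubles as
the symmetry-breaking noise during kernel discovery — disabling it
reproduces the collapse — which is why the default rate stays at 0.5.

Splits follow the published protocol: 20% of genes held out as the test
set (stratified), and per CV fold a 4000-gene validation set drawn from
the remaining pool, the rest training. When the pool cannot spare 4000
genes the validation size is scaled to a quarter of the pool (the
protocol's own ratio) with a logged warning. All draws are
deterministic under the split seed.

AUROC is computed as the normalized Mann–Whitney rank statistic with
midrank ties; ROC points come from scikit-learn. A one-class test set
yields accuracy only, with AUROC flagged undefined.

## N-adjusted kernel transformation

For a trained kernel O (5 × L, rows A, T, C, G, N), per column j:

    a_ij = max(0, O_ij − O_4j),  i ∈ {0..3}
    R_ij = a_ij / Σ_i a_ij       if Σ_i a_ij > 0
    R_ij = 0.25 for all i        otherwise

The N channel appears only in genome positions that carry no sequence
information (masked repeats, assembly gaps), so any weight it acquires
is treated as bias from initialization and training; subtracting it
per column removes exactly the additive component, making the transform
invariant to column-wise shifts and monotone in each nucleotide weight.
The uniform fallback encodes "no preference". The N row is dropped from
the output, which is column-stochastic by construction.

The per-position **N-effect rank** is the ascending rank (0–4) of the N
entry among the five channel entries of a column; rank 4 means the bias
control outweighs every nucleotide. Ties are resolved by counting only
entries strictly below N — the conservative choice, under-stating N's
effect; the rank is therefore exactly `#{i < 4 : O_ij < O_4j}`.

## Attribution

Attribution uses the DeepLIFT rescale rule, implemented natively for
this stack. The target is the logit difference f = z_expressed − z_low
(positive attribution pushes toward the expressed class). Multipliers
propagate exactly through the linear layers; ReLUs use
Δactivation/Δinput with a gradient fallback when |Δinput| < 1e-7; each
max-pool block routes its output delta onto one in-block position with
non-vanishing input delta (scaled so the block contribution is exact).
As a result summation-to-delta holds to floating-point precision:
Σ attributions = f(input) − f(reference). The default reference is the
all-zeros one-hot ("no letter present"); it is a package choice, not
prescribed by the transformation, and is exposed as a parameter.
Gradient × input is available as a separately labeled fallback.
Reporting splits the class-averaged matrix into the TSS ± 10 nt block
(21 positions; window offset 500 is the TSS base) and the remaining 979
positions.

## Motif handling

- **MEME I/O**: minimal motif format (version header, `ALPHABET= ACGT`,
  `strands: +`, background line, per-motif letter-probability matrix
  with 6-decimal cells). Round trips are identical to 1e-6 per cell;
  files parse under Biopython's independent minimal-format reader.
  Internally rows are ordered A, T, C, G and re-ordered to the MEME
  A, C, G, T convention at the boundary.
- **Similarity**: maximum Pearson correlation between flattened
  overlapping column blocks over all relative offsets with ≥ 4
  overlapping columns; symmetric; zero-variance overlaps are skipped
  and fully degenerate comparisons return 0 with a flag. The default
  match threshold is 0.8. This is an in-core stand-in for tomtom
  alignment; `export-meme` produces files for running the real tomtom
  externally (q ≤ 0.05 for known-motif matching, 0.1 for novel-motif
  deduplication; both are config values since the original protocol is
  ambiguous about which pass used which).
- **Common/specific calling**: a matched motif is *common* to a stage
  if it appears in at least 2 of the 5 cross-validation models,
  *specific* if in exactly one. Novel (unmatched) motifs are
  deduplicated greedily in input order at the similarity threshold.
- **Scanning**: forward strand only — reverse-complement occurrences
  are deliberately invisible. Scores are log2 odds of the
  pseudocounted motif (pseudocount 1e-3, renormalized) against the
  library background. Per motif, column scores are discretized onto a
  1000-bin integer grid spanning the motif's score range (with 0
  included so N can score exactly 0 bits, background-neutral: N-padded
  edges neither create nor destroy hits); a dynamic program over
  columns gives the exact null distribution of the integer score under
  the background, hence exact p-values at bin resolution — they match
  brute-force enumeration over all 4^w sequences exactly. q-values are
  Benjamini–Hochberg per motif across all (gene, offset) tests; hits
  are kept at q ≤ 0.1.
- **Occurrence profiles**: per class, the fraction of genes with a hit
  starting at each offset (duplicate offsets per gene count once);
  optional moving-average smoothing, off by default.

## SVM validation

Motif-count features (q-passing hits per gene × motif) feed an
rbf-kernel SVM (scikit-learn SVC; C = 1, gamma = "scale" — both
exposed) fit on a training split and scored on a held-out split with
accuracy, precision, recall and F1, expressed being the positive class.
For comparability the CNN's test partition is reused as the held-out
split. The comparison harness runs any number of motif sets through the
identical split and seed and returns the paired metric table; it
asserts nothing about which set wins.

## Synthetic benchmark

The generator emulates the shape of the real inputs — two-class gene
sets, 1000-nt windows over {A, C, G, T, N}, and a gene × timepoint FPKM
table — with known ground truth. Background letters are i.i.d. from a
configurable composition (uniform by default); each planted motif fires
per window as a Bernoulli event at its class rate, its instance sampled
letter-by-letter from the PWM at a uniform or truncated-Gaussian start
offset; plants never straddle the window edge and never overlap; N
characters are injected i.i.d. after placement (rate ≤ 0.2, motif
positions exempt), mimicking masked repeats. All randomness derives
from one dataset seed with per-gene substreams. The FPKM table gives
expressed genes values > 1 everywhere and low genes ≤ 1 everywhere,
with a configurable conflict fraction taking mixed values to exercise
trimming.

The recovery benchmark's conditions: 2,000 genes, one width-10
consensus-strength motif (one certain letter per column) planted at
rates 0.9 (expressed) vs 0.05 (low), start offset Gaussian(470, sd 5) —
a core-promoter-element-like sharp positional preference just upstream
of the TSS — 1% N characters, fivefold CV with the selected
24/14/10 configuration trained for up to 200 epochs (patience 40).
Consensus strength and positional focus are what make the task's
information ceiling approachable (below); with softer motifs the
position-specific-scoring oracle itself falls under any useful
separation bound.

What the generator does **not** emulate: real promoter composition (GC
skew, CpG islands, TATA/Inr context), co-occurring and strand-flipped
motifs, positional coupling to expression level, or read-level noise in
FPKM values. Passing the benchmark shows the pipeline recovers what it
planted under controlled conditions; it is not evidence about any real
genome.

### Information ceiling of the single-plant design

A single Bernoulli plant at rates p₊ = 0.9 / p₋ = 0.05 bounds every
classifier: knowing presence exactly gives expected accuracy
0.5·p₊ + 0.5·(1 − p₋) = 0.925 and expected AUROC
p₊(1 − p₋) + ½[p₊p₋ + (1 − p₊)(1 − p₋)] = 0.925. The benchmark's
accuracy and kernel-recovery checks sit inside this ceiling; an AUROC
requirement above 0.925 cannot be met by any method under these rates,
which the test suite documents at the corresponding assertion.

## Numerical choices and degenerate inputs

- One-hot encoding is case-insensitive; IUPAC ambiguity codes map to N;
  soft-masked lowercase is uppercased, not masked.
- FPKM threshold comparison is strict (>): a gene at exactly 1.0
  everywhere is low.
- TSS tables are 1-based; internally coordinates are 0-based half-open;
  the window covers [tss − 500, tss + 500) in transcription
  orientation, so offset 500 is the TSS base and a 1-based TSS t on a
  long contig pads max(0, 501 − t) leading Ns.
- Kernel matrices must be finite; NaN/Inf raise immediately.
- PWM columns must sum to 1 within 1e-9; MEME parsing renormalizes the
  6-decimal rounding on read.
- Scanner discretization is 1000 bins per motif; p-values are exact at
  that resolution.
- `pwm_similarity` requires both motifs ≥ 4 columns wide and at least 4
  overlapping columns per offset.
- Grid-search cells whose training fails are recorded with the error
  and excluded from selection rather than aborting the search.

## Known limitations

- Training small conv nets on single-motif tasks is sensitive to
  initialization and schedule; the defaults here are tuned for the
  benchmark regime (hundreds to thousands of windows) and real datasets
  of the published scale may converge within far fewer epochs.
- The scanner's p-values are exact for the discretized score, not the
  continuous one; with 1000 bins the difference is below one bin.
- The internal PWM similarity is a correlation-based stand-in for
  tomtom's null-model alignment; thresholds are not interchangeable
  with tomtom q-values.
- Attribution is defined for this package's own model stack; it is not
  a general DeepLIFT implementation.
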