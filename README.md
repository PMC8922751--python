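# tssmotif

Predicting gene expression status from promoter sequence, and reading
the motifs back out of the model.

`tssmotif` classifies genes as **expressed** vs **low expressed** from
1000-nt windows centered on the transcription start site (TSS), using a
network with a single convolutional layer:

    conv(5-channel one-hot, F filters, width L) → ReLU → max-pool(P)
    → dropout → dense → ReLU → dense(2) → softmax

The one-hot channels are A, T, C, G and N — N being the masked/cryptic
nucleotide character of genome assemblies. Because the model has only
one convolutional layer, its first-layer kernels act as motif scanners,
and the package's central operation turns a trained 5 × L kernel
`O` directly into a position weight matrix by the **N-adjusted
transformation**: the N channel carries no sequence information, so its
weight is treated as the bias floor left behind by initialization and
training, and for i ∈ {A, T, C, G}:

    R_ij = max(0, O_ij − O_4j) / Σ_i max(0, O_ij − O_4j)

with R_ij = 0.25 for all four nucleotides when every adjusted weight is
zero (no preference at that position). The transform is invariant to
adding a constant to a kernel column — exactly the bias it removes.

Around this core the package provides the full pipeline:

- **synthetic** — planted-motif benchmark generator (two-class windows,
  configurable insertion rates, positional distributions, N noise, and
  a matching synthetic FPKM table with ground truth for every stage);
- **prep** — FPKM thresholding (expressed iff FPKM > 1 at all of a
  stage's timepoints; conflicting genes trimmed), TSS window
  extraction (±500 nt, strand-aware, N-padded at contig edges), 5-letter
  one-hot encoding;
- **cnn** — model building, the published split protocol (20% test,
  4000-gene validation sets, fivefold CV), the 7 × 6 × 5 hyperparameter
  grid (210 configurations), accuracy/ROC/AUROC evaluation and
  true-positive selection;
- **interpret** — the N-adjusted transformation, per-position N-effect
  ranks (0 = N smallest of the five channels, 4 = largest), and
  DeepLIFT-style rescale-rule attribution with exact
  summation-to-delta, reported with the TSS ± 10 nt block split out;
- **motifs** — minimal MEME motif format I/O, offset-aligned Pearson
  PWM similarity, common/specific motif calling across CV folds
  (common = present in ≥ 2 of 5 models), greedy novel-motif
  deduplication, FIMO-style forward-strand scanning with exact
  dynamic-programming p-values and Benjamini–Hochberg q-values
  (hits kept at q ≤ 0.1), and class-conditional occurrence profiles;
- **validate** — rbf-SVM re-prediction of expression status from
  motif-count features (accuracy, precision, recall, F1), with a paired
  harness for comparing motif sets under an identical split.

## Worked example

`examples/kernel_to_pwm.py` transforms a three-column kernel by hand:

```
N-adjusted PWM (rows A,T,C,G; columns sum to 1):
[[0.6667 0.25   1.    ]
 [0.3333 0.25   0.    ]
 [0.     0.25   0.    ]
 [0.     0.25   0.    ]]

N-effect rank per column (4 = N largest): [1 4 0]
```

Column 0 has adjusted weights (0.4, 0.2, 0, 0) → probabilities
(2/3, 1/3, 0, 0); in column 1 every nucleotide weight is below the N
weight, so the position is called uninformative (uniform 0.25) and its
N-effect rank is 4.

`examples/simulate_and_train.py` plants a consensus motif in the
expressed class of a synthetic dataset and trains one fold:

```
trained for 42 epochs
validation accuracy (best): 0.988
test accuracy:              0.963
test AUROC:                 0.995
true positives in test set: 76
```

`examples/scan_and_profile.py` (MEME export → forward-strand scan →
occurrence profile) and `examples/svm_validation.py` (motif counts →
rbf SVM) cover the downstream stages; each prints the quantities it
computes and a line on what they mean.

The same pipeline is available as a thin CLI
(`tssmotif simulate|prep|train|grid|interpret|export-meme|scan|profile|svm|report`),
each stage writing a manifest with input checksums, seed and config
hash.

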