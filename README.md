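# promoterlstm

Promoter prediction from fixed-length DNA windows with a bidirectional
LSTM over triplet index vectors, including the construction of
motif-preserving artificial training negatives and a synthetic
promoter simulator for end-to-end validation.

## The problem

Eukaryotic RNA-Pol-II promoters carry position-specific core elements —
a TATA-box near −30..−25 relative to the transcription start site
(TSS), a CAAT-box near −80..−70, a GC-box near −110..−80. Classifiers
trained against negatives drawn from unrelated genomic regions learn
little more than "does a TATA-like motif occur", which fails on
genomic background that happens to contain such motifs. This toolkit
implements the harder training design: each 300 nt promoter window
(−249..+50, TSS at index 249) is split into 20 blocks of 15 nt and 8
randomly chosen blocks are randomly repositioned, producing a negative
with identical nucleotide composition and largely intact local motif
content but broken positional structure. The model must therefore learn
*where* the signal sits, not merely that it exists.

## The model

A sequence is encoded as its overlapping trinucleotides: the 64
triplets over {A,C,G,T} are indexed 1..64 lexicographically (index 0 =
unknown/padding), so a 300 nt window becomes a vector of 298 integers.
The classifier is

    embedding(65 -> 64) -> BatchNorm -> Bi-LSTM(hidden 128/direction)
    -> flatten(298 x 256 = 76288) -> FC(128) + leaky ReLU -> FC(1) + sigmoid

trained with Adam (lr 0.001, batches of 64) under mean binary
cross-entropy; the kept parameter state is the epoch with minimum
validation loss. The network, its analytic backward pass and Adam are
implemented in NumPy (gradient-checked against finite differences), so
training is deterministic for a fixed seed and runs anywhere NumPy
does.

Threshold metrics (BA, SN, SP, PR, F1, MCC) and the curve areas AUCROC
(trapezoidal, = tie-corrected pairwise concordance) and AUCPR (step
rule, = average precision) are built in. See `docs/methods.md` for the
full model description and the design choices.

## Worked example

```python
import numpy as np
from promoterlstm import (
    SimConfig, generate_benchmark, ModelConfig, TrainConfig, train,
    encode_batch, evaluate,
)

cfg = SimConfig(seed=404)  # 300 nt windows, planted TATA/CAAT/GC boxes
train_ds, val_ds, test_ds = generate_benchmark(cfg, n_per_class=1000, seed=404)

est = train(ModelConfig(), train_ds, val_ds,
            TrainConfig(max_epochs=3, batch_size=64, seed=404))
print("best epoch:", est.best_epoch_)

X = encode_batch(test_ds.sequences, pad_to=298)
report = evaluate(test_ds.labels, est.decision_function(X))
print("AUCROC", round(report.aucroc, 3), "AUCPR", round(report.aucpr, 3),
      "BA", round(report.ba, 3))
```

Output:

```
best epoch: 2
AUCROC 1.0 AUCPR 1.0 BA 0.94
```

The held-out test set (200 sequences: 100 simulated promoters, 100
background) is ranked perfectly — the planted positional motifs at 10%
per-position mutation are fully recoverable — while the balanced
accuracy of 0.94 at the default 0.5 threshold shows the probability
cut-off is still slightly conservative this early in training.

The estimator also follows the scikit-learn contract directly:

```python
from promoterlstm import BiLSTMPromoterClassifier
clf = BiLSTMPromoterClassifier(max_epochs=3, random_state=0)
clf.fit(X_train, y_train)          # X: (n, 298) integer index matrix
clf.predict_proba(X_test)
```

## Command line

Each stage is a subcommand of `promoterlstm`:

```bash
promoterlstm simulate --n-per-class 1000 --seed 1 --out-dir sim/
promoterlstm make-negatives --in promoters.fasta --out negatives.fasta \
    --seed 1 --trace trace.tsv
promoterlstm encode --in seqs.fasta --out vectors.tsv
promoterlstm train --train sim/pos.fasta --train-neg auto \
    --val sim/validation.fasta --val-labels sim/labels.tsv \
    --epochs 3 --seed 1 --out model.ckpt --history history.csv
promoterlstm predict --model model.ckpt --in new.fasta --out preds.tsv
promoterlstm evaluate --model model.ckpt --test sim/test.fasta \
    --labels sim/labels.tsv --out report.json --curves curves.tsv
```

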