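# Methods

## Problem and model

The package classifies fixed-length DNA windows as promoter or
non-promoter. A promoter window is 300 nt, covering biological positions
−249..+50 around the transcription start site (TSS). Internally all
coordinates are 0-based array indices with the TSS at index 249; a
TSS-relative position *p* maps to index `249 + p`. We adopt this
convention because the biological labelling ("+1 is the TSS", no
position 0) spans only 299 positions over −249..+50 and is therefore
off by one against the stated 300 nt length; the array convention keeps
the geometry and removes the ambiguity.

The classifier is a recurrent neural network over overlapping-triplet
index vectors:

1. **Encoding.** A width-3 window slides along the sequence with step 1;
   each trinucleotide is mapped to an integer. The 64 triplets over
   {A,C,G,T} are numbered 1..64 in lexicographic order (AAA=1, TTT=64);
   index 0 is reserved for triplets containing N and for right-padding.
   The assignment of triplets to indices is arbitrary for a freshly
   trained model (the embedding is learned), but fixing and exporting it
   makes runs reproducible and auditable. A 300 nt window yields a
   vector of 298 indices. Ambiguous-base triplets map to 0 rather than
   being dropped so the positional frame is never shifted.

2. **Network.** Embedding (vocabulary 65 → 64 features), batch
   normalization over the 64 embedding features with statistics pooled
   across batch and sequence positions, a single bidirectional LSTM
   with hidden dimension 128 per direction (per-position output width
   256), flattening (298 × 256 = 76288), a fully connected layer to 128
   units with leaky-ReLU activation (slope 0.01), and a final linear
   unit with sigmoid output. One recurrent layer is the only depth
   consistent with a 298 × 256 recurrent output feeding the flatten.
   No dropout is used.

3. **Loss and training.** Mean negative binary cross-entropy
   (probabilities clipped at 1e−7 when computed from probabilities;
   internally the loss and gradient are evaluated from logits, which is
   exact and stable). Adam with learning rate 0.001 (the optimizer's
   conventional default), mini-batches of 64, the last incomplete batch
   kept. Training runs for a fixed number of epochs; after training the
   parameter state from the epoch with minimum validation loss is
   restored (ties break to the earliest epoch). Validation loss is
   computed on the full validation set after each epoch. A global
   gradient-norm clip of 5.0 guards against rare early-training spikes;
   it can be disabled. The decision threshold is 0.5, with probability
   = threshold classified positive (documented "≥" tie rule).

The network, its backward pass and Adam are implemented directly in
NumPy. Analytic gradients for every parameter tensor — embedding,
batch-norm scale/shift, both LSTM directions, both fully connected
layers — are verified against central finite differences in the test
suite (float64, relative tolerance 1e−5). Initialization: Glorot-uniform
weight matrices, zero biases except the LSTM forget-gate bias (set to
1.0, the standard stabilization), standard-normal embedding rows;
everything is seeded, so training is fully deterministic for a fixed
seed on any machine. Weights are float32; losses and optimizer state
are accumulated in float64.

## Artificial negatives

Training negatives are built from the training promoters themselves so
that the classifier cannot succeed by detecting motif presence alone: a
300 nt promoter is split into 20 consecutive blocks of 15 nt, 8 block
indices are drawn uniformly without replacement ("substitutional"), and
a uniform permutation of the selected blocks is written back over the
vacated positions; the other 12 ("conservative") blocks stay in place.
Consequences, all enforced as invariants: the block multiset and hence
the exact mononucleotide composition are conserved; conservative blocks
are bitwise identical to the template; trinucleotide counts can change
only at the 2·(n_blocks−1) junction-spanning windows.

Design points the construction leaves open, and our choices:

- A selected block may land back in its own slot (a uniform permutation
  with fixed points allowed); only the full-identity outcome is
  rejected when `forbid_identity` is set, by redrawing the permutation
  up to `max_resample` (default 100) times. Identity can survive
  resampling only when the selected blocks all have equal content
  (e.g. a homopolymer), which raises a construction error.
- `forbid_identity` requires at least two substitutional blocks; with
  the flag off, zero substitutional blocks is legal and yields the
  identity, which is useful as a control.
- Per-sequence seeds are the 32-bit words of
  `numpy.random.SeedSequence(master_seed).generate_state(n)`, so the
  i-th construction depends only on the master seed and i; any prefix
  or subset of a corpus reproduces independently. Every negative
  carries its full trace (selected indices, permutation, seed).
- Block size, block count and substitutional count are configurable
  (defaults 15/20/8) so the construction generalizes beyond 300 nt.

Validation and test negatives are *not* recombinants; they stand in for
real non-promoter sequences (background draws in the simulator), which
mirrors the intended training design: hard constructed negatives for
learning, genuine negatives for assessment.

## Evaluation metrics

From confusion counts at a threshold: SN = TP/(TP+FN),
SP = TN/(TN+FP), PR = TP/(TP+FP), BA = (SN+SP)/2,
F1 = 2·PR·SN/(PR+SN), MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
Any zero denominator returns 0, a sentinel that keeps each metric inside
its nominal range. Reports round to 2 decimals for display; full
precision is retained internally.

Ranking metrics sweep all distinct score thresholds in descending
order. The ROC area is trapezoidal, which equals the pairwise
concordance probability with half credit for score ties; the test suite
checks this equivalence against a brute-force pair count and against
scikit-learn on random instances. The PR area uses the
interpolation-free step rule Σ precision_i · Δrecall_i (identical to
average precision), so a constant score degenerates to the prevalence.
The step rule is fixed so reported areas are reproducible to the digit.

## Synthetic benchmark

The simulator generates 300 nt windows over a configurable background
composition (uniform by default) and plants core-promoter elements at
their canonical TSS-relative windows: TATA-box at −30..−25, CAAT-box at
−80..−70, GC-box at −110..−80. Only the coordinate windows are
canonical; concrete consensus strings are a simulator choice, taken
from the standard promoter-element literature and exposed in the
config: TATAAA (TATA), GGCCAATCT (CAAT), GGGCGG (GC). Each motif is
left-anchored at its window start (no positional jitter by default) and
each consensus position is independently redrawn from the background
with probability `per_position_mutation_prob` (default 0.1), giving a
per-position consensus match rate of (1−p) + p·q_letter. The TATA
promoter class plants all three elements; the nonTATA class drops the
TATA-box.

`generate_benchmark` assembles balanced train/validation/test splits
(default fractions 0.8/0.1/0.1 of `n_per_class` per class, remainder to
train): positives are simulated promoters; training negatives are block
recombinants of the training positives; validation/test negatives are
background draws. All randomness derives from one seed through named
`SeedSequence` children (simulation, background, negative
construction).

What the simulator does *not* emulate: genomic background structure
(CpG islands, isochores, repeats), species-specific composition, motif
position/strength heterogeneity, or the redundancy structure of real
promoter databases. Passing the end-to-end test therefore demonstrates
that the pipeline can learn planted positional signal under controlled
noise — a correctness check of the machinery, not a claim about
performance on real genomes.

## Problem sizes and numerical choices

- End-to-end checks (acceptance script, end-to-end test) use 1000
  sequences per class (1600/200/200 records per split), 10%
  per-position motif mutation, 3 training epochs at batch size 64 —
  enough for the held-out AUCROC ≥ 0.95 criterion with a comfortable
  margin on a single CPU.
- Batch-norm epsilon 1e−5, momentum 0.1 with unbiased variance in the
  running estimate; BCE probability clip 1e−7; Adam β = (0.9, 0.999),
  ε = 1e−8.
- Splits are stratified per class with `round(fraction · n)` sizes; a
  split that would receive zero members of either class is an error.
- Degenerate inputs: sequences shorter than 3 nt cannot be encoded;
  index vectors containing the unknown index cannot be decoded;
  single-class inputs make ROC (and positive-free inputs make PR)
  undefined and raise rather than returning a sentinel.

## Known limitations

- CPU-only; training cost grows linearly in sequence length and
  quadratically in hidden dimension. The defaults (298 positions,
  hidden 128) train at roughly 40 s/epoch for 1600 sequences on one
  core.
- No redundancy filtering of input sequences is performed; an external
  clustering tool can be applied upstream if needed.
- The model reads absolute position through the flatten layer, which is
  intended (promoter elements are position-specific) but means the
  classifier does not generalize to windows with a differently placed
  TSS anchor.
- Checkpoints store raw parameter arrays (.npz with a JSON config);
  they are implementation-version-specific.
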