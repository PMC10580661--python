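# Methods

## The 2Lk encoding

A strand of length L over {A,C,G,T,N} is tokenized by an outer sliding
window of size k1 (stride 1), giving L − k1 + 1 words. Each word is profiled
by a frequency chaos game representation (FCGR) at resolution k2: a
2^k2 × 2^k2 grid whose cells are in bijection with the 4^k2 possible
k2-mers, flattened row-major into a 4^k2 vector. The encoded strand is the
(L − k1 + 1) × 4^k2 matrix whose row i is the FCGR vector of word i, so the
footprint for L = 375 at (k1=3, k2=2) is 373 × 16 against 375 × 4 for
one-hot, and (3, 3) widens the columns to 64.

Conventions that the encoding fixes but the construction leaves open:

- **Cell ordering.** Cells are indexed by the lexicographic digit code
  A=0, C=1, G=2, T=3 read left to right. Any fixed bijection between k-mers
  and cells carries the same information (a column permutation of the
  encoding); the lexicographic one makes indices auditable by hand.
- **N handling.** A k2-window containing m Ns adds 1/4^m to each of the 4^m
  compatible cells. This conserves the total count at W − k2 + 1 for every
  word (exactly for N-free words, to 1e−9 otherwise) and lets the 5^k1-entry
  lookup table (125 entries at k1 = 3) carry information for ambiguous
  positions instead of dropping them.
- **Raw counts, no scaling.** Rows are occurrence counts, each summing to
  k1 − k2 + 1; for the short words involved, frequency normalization would
  only rescale by a constant.
- **Padding.** Variable-length batches are right-padded with all-zero rows
  and an explicit validity mask; the mask removes padded rows from every
  downstream stage (convolution sites, pooling, attention, recurrence).
- One-hot rows for N are all-zero, keeping the baseline comparable to
  DeepBind-style encoders.

The encoding is deterministic; the whole pipeline factors through a lookup
table over all 5^k1 words, whose size is independent of dataset size.

## Predictor architectures

KDeep is a CNN–BiLSTM binary (or multi-label) classifier over encoded
strands; KDeep+ inserts an attention block between the CNN stack and the
recurrence:

    conv(n_filters, F, valid) → ReLU → maxpool(pool) → dropout →
    [additive attention] → BiLSTM(H per direction) → dropout →
    dense(D, ReLU) → dense(n_outputs, sigmoid)

Valid (un-padded) convolution is deliberate: a filter of width F scanning S
encoded rows visits exactly P = S − F + 1 sites, which is the arithmetic the
motif-extraction stage relies on. Pooling is non-overlapping with window
`pool_size`; trailing sites that do not fill a window are dropped. The
BiLSTM reads the pooled sequence in both directions and the final hidden
states are concatenated. Outputs are independent sigmoids (not a simplex)
trained with mean binary cross-entropy, so multi-label target panels are
supported by widening the last layer.

Defaults (all overridable through `ModelConfig` or the YAML config file):
filter width F = 16 rows, pool 13, dropout 0.2 after pooling and 0.5 after
the BiLSTM, H = 32 LSTM units per direction (320 and 320 filters for the
DNA-scale preset), dense width 128, Adam at 1e−3, early stopping on the
monitored loss with patience 5. These follow DanQ-family conventions for
this model class.

**Attention.** Single-head additive attention over pooled positions:
e_t = v·tanh(W h_t + b), α = softmax(e) restricted to valid positions, and
the BiLSTM consumes h_t α_t. The scores α (non-negative, summing to 1 per
strand) are exposed for heatmaps. The hidden width of the scoring MLP is
tied to the filter count. Placing attention after pooling (rather than
before) keeps the score vector short enough to read as a heatmap and leaves
the P = S − F + 1 scanning arithmetic untouched.

**Implementation.** The network is written directly in numpy — an im2col
convolution, masked max-pooling, explicit BPTT through both LSTM directions,
and Adam — with gradients derived by hand and verified against central
differences in the test suite (relative tolerance 1e−4 across every
parameter block, with and without attention, including variable-length
masking). Inference is deterministic (dropout off); training is
reproducible bit-for-bit for a fixed config seed on a single thread.
Internal computation is float64; encoded tensors are stored float32 (counts
are small integers, so no precision is at risk).

## Motif extraction

For each first-layer filter, every strand is scanned at its P sites with
the plain inner product of the filter against the spanned rows (no bias, no
ReLU), and the maximal-activation site is taken, ties to the leftmost. A
site is *valid* when its activation reaches `activation_fraction` (default
0.5) of that filter's maximum over the scanned set — the DeepBind
convention; a fraction of 0 keeps one site per strand unconditionally, and
with a positive fraction a filter that is never positive contributes no
sites. Each valid site p decodes to the nucleotide substring at positions
p … p + F + k1 − 2: a filter spanning F consecutive k1-words covers
W = F + k1 − 1 bases. Substrings are tallied into a position frequency
matrix (N positions contribute nothing; column totals are tracked), and the
PWM is (count + c) / (column_total + 4c) with pseudocount c = 0.25, so a
filter with no valid sites still emits a (uniform) motif and the motif
count always equals the filter count. Motifs are written in MEME minimal
format (uniform background; RNA mode writes the T row under U) for
comparison tools such as TOMTOM. The recurrent layers' contribution is
ignored during interpretation; only the first convolution layer is read.

## Synthetic data

`simulate` emulates binding-site benchmark structure: i.i.d. background
with a chosen GC content, fixed or uniformly drawn lengths, and one
PWM-sampled motif instance overwritten into each positive (uniform or
centered placement), with ground-truth implant positions retained.
Deliberately absent: Markov background structure, read-level artifacts,
crosslink biases, multiple or reverse-complement motif instances, and
secondary structure. Passing recovery tests therefore demonstrate that the
pipeline learns and localizes a planted sequence signal, not that it
matches benchmark performance on real CLIP-seq or chromatin data.

**Default motif calibration.** The default implant is 8 nt wide with 0.95
probability on the consensus base per column. The dominant probability was
set from an information-theoretic calculation rather than from model runs:
with 101-nt strands and uniform implant position, the Bayes-optimal
detector (log-sum-exp of the PWM log-likelihood ratio over implant
positions) achieves auROC ≈ 0.91 at a dominant probability of 0.85 —
i.e. a 0.9 recovery threshold would sit at the ceiling no model can
exceed — and ≈ 0.98 at 0.95, which leaves a small trained model clear
headroom. The recovery experiments use 1000 + 1000 strands of 101 nt at GC
0.5, a 16-filter model, 10 epochs at batch size 32 and learning rate 0.01,
with an 80/20 train/test split; these sizes run in seconds per fit and
represent the smallest problem on which recovery is comfortably
demonstrable.

## Metrics

auROC is the rank statistic (probability a positive outranks a negative,
ties at 1/2); auPRC is step-wise average precision with no interpolation —
the conservative standard. Both are computed by scikit-learn and verified
in the tests against independent brute-force pairwise-counting and
threshold-enumeration oracles. Single-class inputs raise rather than
defaulting to 0.5; degenerate targets are flagged and excluded from macro
averages.

## Numerical and degenerate-input choices

- Argmax ties (pooling and motif harvesting) resolve to the leftmost site.
- The softmax in attention subtracts the per-strand maximum and masks
  invalid positions at −inf before exponentiation.
- Training aborts with a diagnostic on non-finite loss; shape mismatches are
  rejected before the first step.
- A pooled window with no valid site (fully padded) contributes a zero
  feature and is masked from attention and recurrence.
- FASTA writing wraps at 80 columns; reading accepts any wrapping, empty
  files yield empty collections, and sequence data before any header is a
  parse error with the line number.

## Known limitations

- CPU-scale only: the numpy implementation trains small models in seconds
  but is not suited to million-sample panels.
- The FCGR corner geometry is a fixed lexicographic convention; tools
  assuming a specific chaos-game corner assignment will see a column
  permutation.
- Interpretation covers first-layer filters and attention scores only; the
  recurrence's role in predictions is not attributed.
- Reverse-complement symmetry is not modeled in the encoder, the predictor,
  or the motif aligner.
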