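# Methods

## Problem setting

N6-methyladenosine (m6A) is deposited at adenosines within the DRACH
consensus (D ∈ {A,G,U}, R ∈ {A,G}, A, C, H ∈ {A,C,U}; 18 distinct 5-mers).
Single-nucleotide-resolution technologies (miCLIP, m6A-REF-seq, MAZTER-seq)
yield per-site positive labels on transcripts; the classification task is to
decide, for an A-centered sequence window in DRACH context, whether the
central adenosine is methylated. Because the DRACH constraint applies to
both classes, the discriminative signal necessarily lies in the flanking
sequence composition.

## Dataset construction

Callers supply mature-mRNA transcript sequences and 0-based site
coordinates; genome-to-transcript mapping is out of scope. The pipeline:

1. **Positive windows.** Each positive site is expanded to a (2·flank+1)-nt
   window (default flank 100, so 201 nt) centered on the adenosine. Sites
   whose window overruns the transcript, whose central base is not A, or
   whose central 5-mer fails DRACH are rejected with a reason code rather
   than padded — padding would force an arbitrary convention for
   out-of-alphabet positions into the encoder, and rejected sites are logged
   so callers can audit losses.
2. **Negative sampling.** All DRACH-context adenosines at least
   `min_distance` (default 200) nt from every positive on the same
   transcript are enumerated, then uniformly subsampled (seeded) to the
   positive count, yielding a balanced set. Enumerate-then-subsample makes
   the candidate set explicit and the draw reproducible.
3. **Redundancy reduction.** Since all windows are equal-length and aligned
   on the central A, sequence identity is defined as the ungapped
   positionwise match fraction, and a greedy first-come scan discards any
   window with identity ≥ 0.8 to an already-retained one. This is
   deterministic, dependency-free, and conservative for centered windows
   (an alignment-based identity could only be higher, never lower, so the
   ungapped rule removes at least as much redundancy at the same threshold).
   Redundancy is removed on the pooled positive+negative set per condition.
4. **Split.** A seeded, label-stratified 9:1 split; per class,
   round(0.9·n) windows go to train. A class with fewer than two members is
   kept whole in train with a warning.

## ENAC encoding

A sliding window of length 2 with stride 1 maps each length-L sequence to an
(L−1)×4 matrix whose row *i* holds the nucleotide frequencies of positions
{i, i+1}, in fixed channel order A, C, G, U. Rows sum to 1 and take values
in {0, 0.5, 1}. Given a known central adenosine the encoding is invertible
(the overlap between consecutive rows pins the sequence down; the only
ambiguous case, a fully alternating two-letter sequence, is excluded by the
central-A constraint), so no sequence information is lost. The channel
order is recorded in all serialized artifacts.

## Classifier

Architecture: stacked blocks of 1-D convolution (valid padding, along the
encoded-row axis, 4 input channels) → ReLU → non-overlapping max-pool →
dropout, then flatten, one or more fully connected ReLU+dropout layers, and
a single sigmoid output. Loss is binary cross-entropy, optimized with Adam;
parameters are He-initialized from the model seed, and data shuffling and
dropout draw from the same seeded generator, so config + data + seed
reproduce identical weights and predictions bit-for-bit. Early stopping on
a stratified validation holdout is available but off by default.

Forward and backward passes are written directly in NumPy. This is a
deliberate design: the same hand-derived backward pass powers training and
the input-gradient attribution below, the whole dependency footprint stays
within the scientific Python stack, and training the default problem sizes
takes well under a minute per model on one CPU. The backward pass is
verified against central finite differences in the test suite.

Capacity follows data volume via three presets, all with 64 filters in the
first convolutional layer (filter-level interpretation operates on this
layer, and 64 detectors leave room for redundant and rare motifs):

| preset | training size | conv blocks | head | lr |
|---|---|---|---|---|
| small | < 10 000 | 64 filters × 7 rows, pool 31, dropout 0.25 | FC 32 | 2e-3 |
| medium | < 50 000 | 64×7 pool 4 + 32×5 pool 4 | FC 64 | 1e-3 |
| large | ≥ 50 000 | 64×7 + 64×5, pool 2, dropout 0.3 | FC 128+32 | 1e-3 |

The small preset's wide pooling (31 encoded rows, i.e. roughly a third of a
101-nt window's convolution output) is what a motif that floats within the
flanks calls for: it makes the detector nearly translation-invariant while
keeping three coarse position bins, and it shrinks the head to ~8 k
parameters, which suits a few thousand training windows. A kernel of 7
encoded rows covers 8 nt, enough to span a 5-mer motif plus context.
Stratified 5-fold cross-validation (selection metric: mean validation AUC)
is provided for config grids; the best config is refit on all training data.

## Evaluation

Threshold metrics (threshold 0.5, ties called positive): sensitivity,
specificity, accuracy, and MCC; any zero denominator is reported as 0 and
flagged degenerate instead of raising. Threshold-free: ROC AUC and average
precision (step-wise area under the precision–recall curve). The transfer
matrix applies every condition's fitted model to every condition's
independent test set (rows: predictors; columns: datasets) with per-cell
NaN on shape mismatch.

## Interpretation

**Filter motifs.** For each first-layer filter, the threshold is half the
filter's maximum post-ReLU activation over the entire test set (not per
sequence — a global threshold makes counts comparable across sequences);
placements strictly above it contribute the covered nucleotide sub-sequence.
A filter spanning k encoded rows covers k+1 nucleotides (window 2), so
motifs live in nucleotide space. Sub-sequences are stacked into a PFM;
a filter with no activations yields a uniform PFM with support 0.

**Activated amount** = above-threshold placements across the test set
divided by the number of test sequences. **Impact score** (virtual pruning)
= zero the filter's weights and bias, record the mean absolute change in
predicted probability, restore the weights (the operation is pure; a signed
variant is available via a flag). Mean absolute probability change was
chosen over a signed mean (which cancels) and over label-flip counts (too
coarse for small test sets); the AUC drop under the same nullification is
computed alongside as a ranking-sensitive secondary statistic. Note that
with 64 partially redundant filters, single-filter pruning often leaves the
ranking nearly unchanged, so impact scores and AUC drops correlate only
weakly — both are reported rather than conflated.

**Motif comparison.** Pairwise Pearson correlation of flattened PFMs
(undefined for constant matrices, reported as NaN), best-offset PCC for
motifs of unequal length, and average-linkage hierarchical clustering at
distance 1−PCC (average linkage because single linkage chains highly
similar filter motifs into one cluster). PFMs export to MEME minimal
format (RNA alphabet) for use with motif-comparison tools.

**ISM attribution (forward).** Each position is substituted with the three
alternative nucleotides; each mutant is re-encoded (the two encoded rows
overlapping the position change) and rescored. Map entry (b, i) =
score(mutant) − score(original), 0 at the observed base. Sign convention:
mutant minus original, so a negative entry means the observed base supports
the prediction. Scores default to the sigmoid probability; the pre-sigmoid
logit is available via a flag.

**Gradient attribution (backward).** The gradient of the output w.r.t. the
(L−1)×4 encoded input, re-projected to 4×L by summing over the encoded rows
covering each nucleotide position and scaling by 1/window — the adjoint of
how the encoder spreads one nucleotide's identity over `window` frequency
entries. On a linear scorer over ENAC features this projection is exact:
ISM equals the closed-form weight difference and the projected gradient
equals the closed-form weight projection, an identity the tests assert to
float precision.

**Global profiles.** Attribution maps are averaged over samples, then
reduced per position by the channel-wise absolute sum (the mean-then-abs
order preserves cancellation across samples; abs-then-mean would not). The
filter-based analogue counts, per position, activated sub-sequences
covering it, accumulated over filters and averaged per sequence.

## Synthetic data

The generator emulates the balanced DRACH-window benchmarks: each sample is
background sequence (default uniform; configurable skew) with the central
5-mer drawn uniformly from the 18 DRACH 5-mers — identically in both
classes, so classes are exchangeable at the center by construction.
Positives additionally receive each planted motif with its insertion rate
at an offset drawn from its distribution (fixed or uniform, never
overlapping the central 5-mer), sampled per-position from the motif PFM.
Ground-truth planted spans are recorded per sample. A transcript-level
generator plants positive sites (minimum spacing via sorted jittered
placement, which guarantees feasibility whenever the transcript is long
enough) to exercise the full dataset pipeline.

What the generator does *not* emulate: transcriptome-realistic nucleotide
composition and isoform structure, secondary structure, clustered or
co-occurring m6A sites, technology-specific label noise, and any dependence
of the signal on the central 5-mer identity. Passing tests therefore show
that the pipeline recovers flanking-sequence signals it was built to
detect under controlled conditions — not that real m6A data reach any
particular accuracy.

## Reference study conditions

The reproduction script and the end-to-end tests use: 2000+2000 windows of
101 nt, the GGACU consensus planted in the 5′ flank (uniform offset over
the whole flank, insertion rate 0.9), seed-stratified 9:1 split, the small
preset for at most 20 epochs; a matched null condition with insertion rate
0; and a three-condition transfer design (1500+1500 per condition, 15
epochs) where two conditions share the planted motif and the third carries
UCCUC instead. 101-nt windows keep a single experiment around a minute on
one CPU while leaving ~48 nt of flank, ample for a floating 5-mer; the
insertion rate of 0.9 plus the ~9 % chance rate of GGACU in background
places the achievable AUC near 0.93, so observed AUCs ≈ 0.91–0.94 indicate
the classifier extracts essentially all available signal.

## Numerical choices and edge cases

- Classification ties (p = 0.5) count as positive calls.
- Degenerate confusion denominators: metric = 0 plus an explicit flag.
- Activation ties at the filter threshold are excluded (strict >).
- Uniform PFMs have undefined PCC; they are excluded from clustering with a
  warning and labeled 0.
- Dropout is inverted (scaling at train time); inference is deterministic.
- BCE probabilities are clipped at 1e-12 for log stability.
- Max-pool remainders (length not divisible by pool) are truncated.
- Checkpoints are a single JSON file (config + weights + history), loadable
  without pickle.

## Known limitations

- The NumPy engine targets small CNNs on CPUs; it does not scale to deep
  architectures or GPU training.
- Greedy redundancy reduction is order-dependent (first-come retention), as
  is any greedy clustering at a fixed threshold.
- The impact score quantifies prediction *change*, not performance loss;
  use the accompanying AUC drop when ranking filters by usefulness.
- ISM re-encodes and rescores 3L mutants per sequence; attribution over
  very large test sets is the slowest step of the pipeline.
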