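# Methods

## Problem and model

CTCF/cohesin-bound insulator loops partition chromatin and shield genes from
outside enhancers. `insuloop` models the DNA sequence determinants of such
loops with a stack of five classifiers and uses the trained stack to score
the impact of non-coding variants on loop probability:

1. **CNN anchor model** — a dilated convolutional network over a one-hot
   encoded anchor window (default 4000 bases, channels A/C/G/T/N): a 17x5
   convolution (256 filters, full channel depth), batch normalization, leaky
   ReLU (slope 0.2), dropout 0.3; three parallel dilated convolutions
   (dilation rates 1, 3, 7; 512 filters of width 5) whose outputs are
   concatenated, batch-normalized, activated, global-max-pooled and dropped
   out; dense layers of 256 and 128 units; a sigmoid output.
2. **RNN anchor model** — two stacked bidirectional LSTM layers (64 units
   per direction, dropout 0.2 after each) over the central 800 bases of the
   anchor, a time-distributed linear map flattened per position, and the
   same dense head. The window restriction keeps recurrent cost bounded.
3. **Combined anchor model** — both trunks with their dense heads stripped;
   the pooled CNN features and flattened RNN features feed a new dense head
   (512, 256). Trunks are frozen by default once pretrained.
4. **Anchor orientation model** — the combined architecture with a fresh
   dense head (256, 128), trained to separate left (negative) from right
   (positive) loop anchors. Its trunks are initialized from the anchor
   model and fine-tuned: features learned for anchor-vs-non-anchor carry no
   information about loop side, so a frozen-trunk orientation model would be
   ill-posed.
5. **Loop model** — consumes a pair of encoded anchors. The anchor and
   orientation feature extractors are applied to each side with shared
   weights; the two feature vectors and the four component probabilities
   (anchor and orientation score per side) feed a new dense head (512, 256).
   Pretrained components are frozen by default (configurable), which makes
   training a cheap head fit on precomputed features.

All models are trained with binary cross-entropy minimized by RMSprop and
report the parameters of the best validation-loss epoch. Every layer is
implemented in NumPy inside the package (`insuloop.nn`); gradient
correctness is pinned by finite-difference tests. Batch-norm/leaky-ReLU/
max-pooling are per-channel operations, so the implementation normalizes and
pools each dilated branch separately before concatenating — element-for-
element identical to concatenating first, but far cheaper on
memory-bandwidth-limited hosts.

## Dataset construction

* **Coordinates** are 0-based half-open everywhere; VCF positions and FIMO
  coordinates are converted on ingest. Non-ACGT letters become N.
* **Anchor normalization**: two anchors merge (interval union) when their
  overlap exceeds 0.9x the length of either; merging repeats in coordinate
  order to a fixpoint, which makes the result input-order independent. The
  merged peak center is the interval midpoint unless peak summits are
  supplied, in which case the summit of the longest contributing peak wins.
* **Standardization**: anchors are trimmed/expanded to 4000 bases centered
  at their peaks; windows hanging off a contig edge are N-padded rather than
  shifted so the peak stays at the window center.
* **Negative anchors**: type 1 = bound peaks (containing a motif) that
  anchor no loop; type 2 = motif occurrences under no peak; type 3 =
  motif-free windows, sampled at a configurable stride with a seeded RNG
  (exhaustive enumeration is available for toy genomes).
* **Negative loops**: pairs constrained to spans at most the 75th percentile
  (linear interpolation) of true-loop spans; types 1/2/3 pair true anchors
  with convergent/tandem/divergent motif orientation, type 4 pairs a true
  anchor with a motif-bearing non-anchor convergently, type 5 with a
  motif-free non-anchor. An anchor's orientation class is the strand of its
  best-p-value contained motif hit.
* **Balancing**: training and validation sets have equal positive and
  negative counts, negatives drawn 50:30:20 (anchor task) or
  50:10:10:20:10 (loop task) by type with largest-remainder allocation and a
  seeded RNG; exhausted pools renormalize with a log. Test partitions keep
  every negative. Reverse-complement augmentation doubles training sets
  (for loops both anchors are complemented and sides swapped).
* **Splits** are by whole chromosome (defaults: chr7+chr8 test, chr16
  validation), so no positional leakage is possible.

## FIMO filtering

Motif hits are kept when p < 5e-5, strictly: the stated threshold is treated
as an exclusive cutoff, pinned by tests at the boundary.

## Variant engine

Variants are applied to a wide reference slab around each anchor window,
right-to-left; overlapping variants within one sample keep the leftmost and
reject the rest (logged), and reference-mismatching records are rejected
(logged). The edited coordinate of the original window center is tracked and
the fixed-length window re-cut around it ("center-anchored" restoration):
net deletions pull reference in from the flanks, insertions push it out, and
the peak stays centered so scan/CAM coordinates remain meaningful. A
deletion larger than the window pulls in distal reference. Samples with no
variant overlapping either anchor reuse the reference probability
bit-for-bit, making the zero-variant delta exactly 0.

Loop disruption is called at the 90th percentile (linear interpolation) of
positive probability reductions pooled over all (loop, sample) pairs;
recurrence uses floor(fraction x cohort size) as the minimum patient count
(configurable to ceiling), and a gene belongs to a loop only when its
interval is fully contained between the outer anchor bounds.

## Class activation maps

The final convolutional feature maps (the concatenated dilated branches,
after activation, before pooling) are weighted by the gradient of the output
logit with respect to the pooled feature vector and summed per position.
For a single linear class head this reduces exactly to the classic CAM
weighting; the gradient form extends it to this architecture's two-layer
head and global *max* pooling, and keeps the zero-weight and linear-scaling
identities testable. Profiles are linearly upsampled from feature-map to
base resolution and a LOESS trend is fitted (span fraction 0.4, local
linear, tricube-weighted, no robustness iterations, via statsmodels). Peaks
are called on the trend-corrected profile (raw minus LOESS): at span 0.4
over a kilobase anchor the LOESS curve is a baseline hundreds of bases
wide, so motif-scale attribution structure lives in the residual — on
trained models the raw profile's maxima sit directly on planted motifs
while the trend's maxima do not. A base is a peak when it is the strict
maximum of its centered 40-base window and exceeds the 0.75 profile
quantile (window, quantile and detrending all configurable); adjacent
qualifying bases collapse to the single highest.

## Synthetic grammar

The generator plants a learnable loop grammar on random-background
chromosomes (GC fraction 0.41):

* **True anchors** carry an oriented 19-base core motif (the CTCF-motif
  analog), an 8-base cofactor motif (the cohesin co-binding analog), and a
  10-base side signature marking left vs right loop ends. Loops are
  convergent with probability 0.85 (left anchor core on +, right on -),
  otherwise tandem.
* **Bound decoys** (peak, no loop) carry the core motif and a random side
  signature but no cofactor, so anchor-vs-decoy discrimination genuinely
  requires the cofactor. **Motif-only decoys** are the same without a peak.
  **Background windows** carry no core motif, but a fraction (0.30) contain
  a stray cofactor — so neither motif alone identifies an anchor, and a
  trained model must weight both. This last property is what makes the
  single-base deletion scan well-posed: the scan region around a core motif
  contains exactly one informative element, and the model provably depends
  on it.
* **Degeneracy**: every planted instance mutates each base with probability
  0.05, and motif-table p-values are a deterministic function of edit
  distance (1e-6 x 8^edits), crossing the FIMO threshold at three edits.
  Spurious super-threshold rows exercise the p-value filter.
* **Multi-motif anchors**: with probability 0.9 a true anchor carries a
  second, better-scoring core motif on a uniformly random strand. The
  best-hit orientation class is then only weakly coupled to loop side,
  mirroring real anchors (where roughly half contain several motifs and
  orientation alone cannot pair loops); loop pairing must rely on the side
  signatures, which keeps the convergent non-loop task hard but beatable.
* **Variants**: each synthetic sample receives motif-disrupting variants
  (SNVs or short deletions inside planted core/cofactor motifs of loop
  anchors) and matched neutral variants placed inside anchor windows at
  least 30 bases from any planted element. Neutral variants inside windows
  (rather than in intergenic background) give the ablation comparison a
  non-trivial null distribution; they are substitutions only, because an
  indel anywhere upstream of the planted elements shifts every downstream
  base relative to the recurrent model's positional grid — a register
  change, not a content-neutral edit.

What the grammar does **not** emulate: realistic base composition and repeat
structure, CTCF position-weight-matrix binding energetics, peak-calling
noise, interconnected/nested loops, structural variants. Passing recovery
tests therefore demonstrates that the pipeline can learn and localize a
planted sequence grammar end to end — not that it attains any particular
accuracy on real ChIA-PET data.

## Perturbation recovery

The known-deletion validation is miniaturized on the first five held-out
loops: a saturation scan of single-base deletions across a 400-base region
containing the left anchor's planted core motif (counting top-10 deltas
inside the motif +/- 5 bases), and an ablation of the anchor's full planted
motif module — core plus cofactor, the analog of deleting a whole binding
element — compared against a matched neutral null of single substitutions
in the same anchor windows at least 30 bases from any planted element.
Medians across the five loops are reported because individual loops sit at
different points of the probability scale and respond with very different
magnitudes; the null pools all five windows. The CAM-peak enrichment test
runs at peak quantile 0.99: the default 0.75 quantile yields an almost
uniform lattice of window maxima (informative for counting peaks, not for
localization), while only the sharpest attribution spikes — which sit on
the planted motifs — survive the stricter threshold.

## Desk-scale recovery study

The study conditions (in `insuloop.experiments.StudyConfig`): 1000 loops
(2000 true anchors) over ten 1.4-Mb chromosomes, anchors of 1000 bases with
a 200-base recurrent window, model widths scaled by 1/8, spans log-uniform
on [4, 20] kb, two held-out test chromosomes and one validation chromosome.
Strand augmentation is off in this study (evaluation uses a single strand
convention; the augmentation path is exercised by its own tests). These
sizes keep each task statistically well-posed while the whole study trains
in minutes on one CPU.

Training schedule: RMSprop at learning rate 3e-3, batch 64 (the library
default learning rate is 1e-3; the study overrides it through the exposed
config). The CNN trains in two stages: 24 epochs on a balanced 1200-sample
subset of the training set, then 4 epochs on the full set. Under global max
pooling, motif tasks show a long near-zero-gradient plateau until some
filter locks onto the discriminative k-mer, and the plateau breaks through
sample repetition — a compact first stage crosses it at a fraction of the
full-set epoch cost, and the short second stage refines the working
solution on all data. The recurrent model (6 epochs), the combined and loop
heads (60 cheap epochs on precomputed frozen features) and the fine-tuned
orientation model (6 epochs) train conventionally. Early stopping on
validation loss with patience 8; best-validation-loss parameters retained.

## Numerical choices

* float32 parameters and activations; predictions are deterministic and
  bit-stable across save/load.
* Average precision uses threshold-block tie handling (tied scores form one
  step), under which a constant scorer scores exactly the positive
  prevalence; verified against a brute-force staircase oracle.
* The equal-precision-recall threshold scans observed scores
  (prediction positive when score >= cutoff) and minimizes
  |precision - recall|; ties break toward higher recall, then toward the
  higher threshold.
* Percentiles use NumPy's linear interpolation between order statistics.
* He initialization for convolutional/dense weights, Glorot for recurrent
  ones, forget-gate bias 1; all randomness flows from caller-supplied seeds.
* First-layer convolution filters additionally receive a structured one-hot
  boost so each starts as a random k-mer detector (`kmer_init_boost`,
  default 0.3). Under global max pooling, purely random filters produce
  near-constant pooled activations and gradient flow stalls for hundreds of
  updates; k-mer seeding — the PWM-style initialization common in sequence
  CNNs, here with random k-mers rather than known motifs — removes that
  dead plateau without telling the model anything about the data.
* Degenerate inputs are pinned by tests: empty windows, windows entirely off
  a contig (all N), loops whose anchors merge to one region (dropped),
  negative pools too small for the mix (renormalized), no positive
  reductions (error).

## Known limitations

* The NumPy training loop is single-threaded and bandwidth-bound; full-size
  (scale 1) training on real genome-wide data is out of reach — the
  full-size architecture is constructed and verified structurally, but only
  desk-scale models are trained here.
* CAM is computed with gradient weights under global max pooling; other
  attribution conventions would shift per-base scores (the peak caller's
  window/quantile rule is configurable for this reason).
* The loop model's achievable accuracy on convergent non-loops is bounded by
  construction: a fraction of convergent true-anchor pairs is
  indistinguishable from real loops (as in real data, where unobserved true
  loops contaminate that negative set).
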