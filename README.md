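# insuloop

Sequence-based modeling of CTCF/cohesin **insulator loops** and prediction of
the impact of non-coding variants (SNVs, indels, deletions) on loop
probability.

Insulator loops are chromatin loops whose two anchors are co-bound by CTCF
and the cohesin complex; they shield genes from outside enhancers, and
non-coding mutations at their anchors can rewire gene regulation in cancer.
`insuloop` learns the sequence determinants of such loops directly from
anchor DNA and then asks, for any set of patient variants: *how much does
each loop's predicted probability drop when the variants are applied?*

The package is aimed at regulatory-genomics researchers who have loop calls
(ChIA-PET BEDPE), CTCF binding peaks (BED/narrowPeak), motif scans (FIMO
TSV), a reference genome (FASTA) and somatic variants (VCF) — and at method
developers who want a fully synthetic, label-complete benchmark for this
class of models.

## The model stack

Five classifiers, all emitting probabilities in [0, 1]:

| model | input | task |
|---|---|---|
| CNN anchor | 4000-base one-hot window (m x 5) | anchor vs non-anchor |
| RNN anchor | central 800 bases | anchor vs non-anchor |
| combined anchor | CNN + RNN features | anchor vs non-anchor |
| orientation | anchor window | left vs right loop end |
| loop | pair of anchor windows | loop vs non-loop |

The CNN applies a 17x5 convolution (256 filters), then three parallel
dilated convolutions (rates 1, 3, 7; 512 filters of width 5), each followed
by batch normalization, leaky ReLU (0.2), global max pooling and dropout;
the RNN stacks two bidirectional LSTM layers (64 units, dropout 0.2). The
combined model concatenates both feature sets under a new dense head
(512, 256); the orientation model retrains a fresh head (256, 128) with
fine-tuned trunks; the loop model applies the anchor and orientation
extractors to both anchors and combines features with the component
probabilities. Training minimizes binary cross-entropy with RMSprop and
keeps best-validation-loss weights. Negative classes follow the standard
taxonomy: three non-anchor types (bound-but-unlooped peaks, unbound motifs,
motif-free regions, mixed 50:30:20) and five non-loop types (convergent /
tandem / divergent true-anchor pairs, convergent true+non-anchor pairs, and
motif-free partners, mixed 50:10:10:20:10, spans capped at the 75th
percentile of true-loop spans). Splits hold out whole chromosomes
(chr7/chr8 test, chr16 validation by default).

The neural-network layers and the training loop are implemented in NumPy
inside the package (`insuloop.nn`) — deterministic, seeded and
finite-difference-tested; no GPU or deep-learning framework is required.

Everything downstream of a trained loop model is in `insuloop.variants`:
center-anchored variant application that always restores the model's fixed
window length, per-(loop, sample) disruption records, single-base saturation
deletion scans, the 90th-percentile disruption threshold and cohort
recurrence summaries. `insuloop.interpretation` adds class-activation-map
attribution with LOESS smoothing and 40-base-window peak calling.

`insuloop.synthetic` generates complete synthetic universes — genome, loops,
anchors, peaks, FIMO-style motif tables, multi-sample VCFs, and per-site
truth labels — with a planted, learnable loop grammar (oriented core motif,
anchor-only cofactor, left/right side signatures, degenerate copies,
orientation-noise motifs). See `docs/methods.md` for the grammar and every
modeling decision.

## Worked example

Simulate a small universe, train a compact CNN anchor model, and score it:

```
insuloop simulate --seed 3 --out bundle/
cat > prep.yaml <<EOF
anchor_length: 1000
test_chroms: [chr4]
val_chroms: [chr3]
seed: 1
EOF
insuloop prepare --loops bundle/loops.bedpe --peaks bundle/peaks.narrowPeak \
    --motifs bundle/motifs.tsv --genome bundle/genome.fa \
    --config prep.yaml --out data/
cat > model.yaml <<EOF
anchor_length: 1000
rnn_window: 200
scale: 0.125
learning_rate: 0.003
max_epochs: 16
EOF
insuloop train --task cnn --data data/ --config model.yaml --seed 2 --out cnn/
insuloop predict --model cnn/ --data data/anchor_test.npz --out scores.tsv
```

The same study, driven from Python at the sizes used by the acceptance
script (1000 loops, 1000-base anchors, width scale 1/8; takes several
minutes):

```python
from insuloop.experiments import run_recovery_study
res = run_recovery_study(seed=7)
print(res["metrics"])
```

prints (seed 7):

```
{'ap_cnn_type1': 0.9451278238459463, 'ap_rnn_type1': 0.6857938073538504,
 'ap_anchor_type1': 0.9518412910710867,
 'anchor_eval_prevalence': 0.5434782608695652, 'anchor_eval_n': 736,
 'ap_orientation': 0.9560246193286548, 'orientation_eval_n': 400,
 'ap_loop_type1': 0.7237284679946533, 'loop_eval_prevalence': 0.5,
 'loop_eval_n': 266}
```

Reading the numbers: `ap_anchor_type1` is the combined anchor model's
average precision separating held-out true anchors from bound decoys
(prevalence ~0.5, so an uninformative model would score ~0.5);
`ap_orientation` separates left from right anchors; `ap_loop_type1` is the
loop model against convergent true-anchor non-loops — the hardest negative
set, whose ceiling is below 1 because some convergent pairs are
sequence-identical to real loops.

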