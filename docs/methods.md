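# Methods

## The screening problem

Trisomy 21 (Down syndrome, DS) triples the copy number of human chromosome 21
(Hsa21), so every Hsa21 locus produces roughly 1.5x the signal of a disomic
genome. An exome genotyping array measures, at each biallelic SNP, two
fluorescence intensities — one per allele (A/B). `trisomap` turns a sample's
per-SNP intensities into two grayscale images ("chromosome SNP maps"), trains
a two-branch convolutional network on the image pair, and reports screening
metrics under a repeated random-split protocol, alongside classical-ML
baselines fitted on the flat intensity table.

## Chromosome SNP maps

A map is laid out gene-by-gene: gene *g* (in a fixed total gene order)
occupies `column_width` adjacent pixel columns; the *s*-th SNP of that gene
sits in row *s*; the SNP's normalized intensity in [0, 1] is the pixel value,
replicated across the gene's columns; everything else is padding
(`fill_value`, default 0 — inert under ReLU convolutions). With the study
geometry of 321 Hsa21 genes and `column_width = 2`, maps are 642 pixels wide;
the height is padded to 642 to match. The encoding is exactly invertible
(`invert_map`) and conserves the intensity sum times `column_width`; both
properties are tested.

The field cannot phase the two physical chromosome homologs from array data,
so the two map streams are the two allele channels (A and B) of one array —
the only measurable two-map decomposition. This is a documented convention,
not a biological claim about homolog separation.

## The bi-stream CNN

Per branch: input -> C1 (16 filters, 3x3, same-padding, ReLU) -> max-pool 2x2
-> dropout 0.25 -> C2 (16, 3x3, ReLU) -> dropout -> C3 (16, 3x3, ReLU) ->
dropout. The two branches merge by channel concatenation (32 channels) into
C4 (16, 3x3, ReLU), followed by max-pool 2x2, dropout, flatten, dense 512
(ReLU, dropout) and a 2-node softmax. Same-padding keeps branch shapes equal
at the merge and yields the clean spatial trace 642 -> 321 -> 160 through the
two pools (pooling floors odd sizes). An element-wise-add merge is available
as a config option. The single-stream ablations keep one branch and the
identical head (C4 then sees 16 input channels).

Training minimizes softmax cross-entropy (two-class cross-entropy with
one-hot labels) with SGD: learning rate 0.01, decay 1e-6 per iteration,
Nesterov momentum 0.9. The engine is pure numpy: im2col + BLAS matmul
convolutions, argmax-routed pooling gradients, inverted dropout; gradients
were verified against central finite differences to ~1e-9 relative error.

Numerical choices that the architecture description leaves open:

- **Initialization**: Glorot-uniform weights, zero biases, seeded.
- **Gradient clipping**: gradients are rescaled when their global L2 norm
  exceeds `clipnorm` (default 5.0). A momentum optimizer at a fixed 0.01
  learning rate occasionally produces a one-batch gradient spike late in
  training (a confidently-fit network meets an unlucky dropout mask), which
  can irreversibly silence the ReLU stack; clipping is inactive in ordinary
  steps and exists solely to make long trainings deterministic-stable. It can
  be disabled (`clipnorm=None`).
- **Epochs / batch size**: unstated upstream; defaults 50 and 16,
  config-exposed. The desk-scale experiments below use 30 epochs, batch 16
  (plateau escape was observed by epoch 19 in every converging desk-scale
  run, so 30 leaves margin while keeping the ten-repeat protocol within
  minutes on one core).
- **Ties**: an exact probability tie predicts control (argmax takes the
  first class).
- **Determinism**: weight init, shuffling and dropout masks all flow from one
  seed; two runs with the same seed and data produce bit-identical histories
  and weights. Inference never applies dropout and is a pure function.

## Synthetic cohorts

The real cohort (378 samples: 63 DS, 315 control; 5458 SNPs on 321 Hsa21
genes) is private, so the simulator is a first-class module and defines the
test conditions. Defaults mirror the study cohort exactly. Per SNP *j*:
MAF_j ~ Beta(0.5, 5) clipped to [0.001, 0.5] (a rare-variant spectrum, as on
an exome array) and gain g_j ~ U[0.8, 1.2]. Per sample: a control draws B
allele count k ~ Binomial(2, MAF_j) and gets channel intensities
A = g_j (2-k)/2 + eps, B = g_j k/2 + eps with eps ~ N(0, 0.08^2) per channel.
A DS sample draws k ~ Binomial(3, MAF_j) with effective copies
c_eff = 2 + alpha and k_eff = k c_eff/3, so A + B telescopes to g_j c_eff/2 —
exactly (2+alpha)/2 times a control's expected total, the 1.5x trisomy dosage
at alpha = 1. Each (SNP, channel) column is then min-max normalized across
the cohort ([0,1]; constant columns map to zero). Sample order is shuffled,
and everything is reproducible from one seed.

Two deliberate simplifications:

- **Exact null at alpha = 0.** The dosage formula alone would leave DS rows
  with a slightly different allele-count variance even at alpha = 0 (a
  Binomial(3)-derived draw scaled by 2/3). The simulator instead routes
  alpha = 0 DS samples through the control path verbatim, so the null label
  carries literally no signal — the property the calibration tests rely on.
- **Channel assignment of the dosage effect** (`dosage_channels`). In the
  default `"both"` mode the dosage scales both channels of a DS sample. In
  `"split"` mode each SNP's dosage effect is carried by one channel only
  (alternating A/B along the SNP index), so a single-stream model sees only
  half of the affected sites — the construction used to probe what fusing the
  two streams adds over either alone.

Not modeled (extension points only): linkage disequilibrium, mosaicism,
partial trisomy, batch effects, per-sample intensity artifacts. Because every
informative SNP is conditionally independent given the class, the synthetic
task is easier than real array data at equal effect size; passing tests show
that the pipeline recovers an engineered dosage signal and is correctly
calibrated under a true null, not that the printed cohort accuracies
transfer.

## Evaluation protocol

Ten parallel experiments; each draws a fresh uniform random 75/25 train/test
split (seed + repeat index; stratified splitting is available but off by
default), trains from scratch, and scores the held-out samples. With DS as
the positive class the report carries per-run confusion counts and accuracy,
precision, recall, F-score, false-positive rate and false-negative rate,
their mean +- SD across runs, and pooled confusion counts over all runs. A
ratio with a zero denominator is reported as 0 and flagged. Two F-scores are
emitted: the positive-class F1 (`f_score`) and a support-weighted average
over both classes (`f_score_weighted`), because published screening tables
sometimes report the latter under the same name; emitting both avoids
guessing.

The classical baselines (C-SVC with one-vs-one decision shape; random forest,
100 trees, entropy criterion, no depth limit; CART decision tree, all
features per split) run through the identical harness on the flat feature
table (both channels concatenated by default; A, B, or A+B summed are
options). SVM kernel and C are scikit-learn defaults (RBF, C=1) — documented
choices, not claims about the original study.

## Desk-scale experiment sizes

The full 642x642 geometry trains only at GPU scale, so the shipped
experiments use two reduced cohort presets, both with 200 samples at the
study's 1:5 DS:control imbalance (33/167), 32 genes, 64x64 maps, alpha = 1
and noise 0.08, with CNNs trained 30 epochs at batch 16:

- **`desk_scale_config`** mirrors the study's SNP density (17 per gene, 544
  sites) and is used for the null-calibration runs (at alpha = 0) and the
  harness-determinism checks. With hundreds of informative sites the dosage
  signal is far above the classification ceiling: every architecture that
  escapes the optimization plateau classifies perfectly, which demonstrates
  signal recovery but makes architecture *comparisons* vacuous.
- **`fusion_benchmark_config`** is built so the two-stream-vs-one-stream
  comparison is informative. Balanced allele frequencies (Beta(8, 8) clipped
  to [0.05, 0.5]) make each channel carry exactly half of the expected dosage
  shift, confounded per SNP by the B-allele-count (genotype) noise; the
  confound cancels only in the fused view because A + B telescopes to
  gain x copies/2. One SNP per gene (32 sites) places the per-channel
  aggregate discriminability near d' ~ 3.6 — below ceiling — while the fused
  view sits near d' ~ 25. On this cohort the ten-repeat protocol yields
  bi-stream 0.998 mean accuracy vs 0.996 (stream A) and 0.954 (stream B):
  the merge recovers information neither branch has alone, which is the
  architectural claim the package exists to test.

At this scale each ten-repeat CNN protocol runs in minutes on one CPU core.

## Known limitations

- An unpruned CART tree (no depth limit, all features per split — the
  configured decision-tree baseline) grows pure leaves on a null cohort and
  therefore predicts classes at roughly the training prior p, capping its
  expected null accuracy at p^2 + (1-p)^2 (~0.72 at the 1:5 imbalance) —
  measurably *below* the majority rate. This is the expected behavior of an
  unpruned tree under class imbalance, not label leakage; the other five
  models predict the majority class at the null and calibrate to it.

- Optimization at the fixed 0.01 learning rate on small cohorts is
  plateau-prone: the network first fits the class prior and only later
  escapes to the dosage features; runs that have not escaped within the epoch
  budget score at the majority rate. Seeds and epoch counts in the shipped
  experiments are fixed and reproducible.
- The weighted-F/accuracy coincidence in published tables cannot be resolved
  from definitions alone; both variants are always reported.
- PNG export quantizes to 8 bits and is for figures only; every training and
  analysis path uses the lossless array container.
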