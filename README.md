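# trisomap

Chromosome SNP-map encoding of genotyping-array intensities and a bi-stream
convolutional network for trisomy-21 (Down syndrome) screening.

## The problem

Trisomy 21 triples the copy number of human chromosome 21 (Hsa21), so every
Hsa21 locus emits roughly 1.5x the fluorescence of a disomic genome on a
genotyping array. Given per-sample, per-SNP normalized intensities for the
two allele channels (A/B) of an exome array — 5458 SNP sites on 321 Hsa21
coding genes in the reference cohort of 378 samples (63 DS, 315 control) —
the task is to classify DS vs control.

`trisomap` is for computational genomicists who want to reproduce, probe or
extend this image-encoding screening approach: it encodes each sample as two
grayscale **chromosome SNP maps** (genes as pixel columns, within-gene SNPs
as rows, pixel value = intensity; 321 genes x 2 pixel columns = 642x642 at
the default geometry), trains a **bi-stream CNN** on the map pair, and
evaluates it against single-stream ablations and classical baselines (C-SVC,
random forest, CART) under a ten-repeat random 75/25-split protocol. Because
the original cohort is private, a **synthetic cohort simulator** with a
tunable trisomy dosage signal (effective copies 2 + alpha; alpha = 1 gives
the biological 1.5x ratio) is a first-class, tested module.

## The model

Per branch: map -> conv C1 (16 filters 3x3, ReLU) -> max-pool 2x2 -> dropout
0.25 -> conv C2 -> dropout -> conv C3 -> dropout. The branches merge by
channel concatenation into conv C4 (16 filters), then max-pool, dropout,
flatten, dense-512 (ReLU, dropout) and a 2-node softmax. Training: SGD,
learning rate 0.01, decay 1e-6, Nesterov momentum 0.9, softmax cross-entropy.
The CNN engine is pure numpy (im2col + BLAS convolutions, finite-difference-
verified gradients, fully seeded); see `docs/methods.md` for the numerical
choices and the simulator's generative model.

## Worked example

```python
from trisomap import (
    BiStreamModelSpec, MapLayout, cnn_protocol, fusion_benchmark_config, simulate_cohort,
)

cohort = simulate_cohort(fusion_benchmark_config(seed=1))  # 200 samples, 64x64 maps
spec = BiStreamModelSpec(input_size=(64, 64), epochs=30, batch_size=16)
report = cnn_protocol(cohort, spec, "bistream", MapLayout(2, 64),
                      n_repeats=10, seed=0)
print(f"accuracy {report.mean['accuracy']:.3f} +- {report.std['accuracy']:.3f}")
print(f"recall   {report.mean['recall']:.3f}  fn_rate {report.mean['fn_rate']:.3f}")
```

prints

```
accuracy 0.998 +- 0.006
recall   0.990  fn_rate 0.010
```

The cohort here is the *fusion benchmark*: each allele channel carries half
of the 1.5x dosage shift, confounded per SNP by the B-allele-count genotype
noise, which cancels only when both channels are combined (A + B is pure
gain x copy-number). Across the ten repeats the bi-stream model misses 1 of
83 held-out DS samples with zero false positives, and it beats both
single-stream ablations (0.996 and 0.954 mean accuracy) — the two-branch
merge is doing real work. At alpha = 0 (a true null) the same protocol stays
at the majority-class rate, confirming calibration.

The same pipeline is scriptable from the shell:

```bash
trisomap simulate --seed 1 --out-dir data/
trisomap build-maps --genotypes data/genotypes.tsv --annotation data/annotation.tsv --out-dir maps/
trisomap evaluate --genotypes data/genotypes.tsv --annotation data/annotation.tsv \
    --labels data/labels.tsv --arch bistream --repeats 10 --seed 0 --out report.json
```

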