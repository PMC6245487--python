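"""Synthetic genotyping-array cohorts with a trisomy-21 copy-dosage signal.

The real study cohort (378 exome-array samples, 5458 Hsa21 SNPs) is private,
so this module generates cohorts with the statistical structure the screening
method assumes: rare-variant minor-allele frequencies, per-SNP multiplicative
gain, additive channel noise, and a chromosome-21 dosage effect that scales a
trisomic sample's raw signal by (2 + alpha) / 2 relative to disomic controls
(alpha = 1 gives the biological 3/2 ratio).

Generative model, per SNP j and sample i:

    MAF_j ~ Beta(maf_shape), clipped to [0.001, 0.5]
    g_j   ~ Uniform(gain_range)                        (per-SNP gain)
    control:  k ~ Binomial(2, MAF_j);  A = g_j (2 - k)/2 + eps,  B = g_j k/2 + eps
    trisomic: k ~ Binomial(3, MAF_j);  effective copies c_eff = 2 + alpha,
              k_eff = k c_eff / 3;     A = g_j (c_eff - k_eff)/2 + eps,
                                       B = g_j k_eff / 2 + eps
    eps ~ Normal(0, noise_sd), independent per channel

so the total raw intensity A + B of a trisomic sample is (2 + alpha)/2 times
that of a control in expectation. Afterwards every (SNP, channel) column is
min-max normalized to [0, 1] across the cohort (a constant column maps to all
zeros), matching how the array intensities are preprocessed.

At alpha = 0 trisomic samples are drawn by the exact control path, so the two
classes are identically distributed and the label carries no signal — the null
construction used for calibration tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .io_formats import CONTROL_LABEL, DS_LABEL, GenotypeDataset, SNPAnnotation

#: Channel-assignment modes for the dosage effect. "both": the full dosage
#: signal appears in both allele channels (default, mirrors total-intensity
#: scaling). "split": each SNP's dosage effect is carried by one channel only,
#: alternating A/B along the SNP index, so neither channel alone sees the full
#: chromosome-wide signal — used to probe the two-stream architecture's
#: advantage over single-stream ablations.
DosageChannels = Literal["both", "split"]


@dataclass
class SyntheticConfig:
    """Cohort-simulation parameters; defaults mirror the study cohort."""

    n_control: int = 315
    n_ds: int = 63
    n_genes: int = 321
    n_snps: int = 5458
    maf_shape: tuple[float, float] = (0.5, 5.0)
    maf_bounds: tuple[float, float] = (0.001, 0.5)
    gain_range: tuple[float, float] = (0.8, 1.2)
    noise_sd: float = 0.08
    dosage_alpha: float = 1.0
    dosage_channels: DosageChannels = "both"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_control, self.n_ds, self.n_genes, self.n_snps) <= 0:
            raise ValueError("all counts must be positive")
        if self.n_snps < self.n_genes:
            raise ValueError("n_snps must be at least n_genes")
        if not 0.0 <= self.dosage_alpha <= 1.0:
            raise ValueError("dosage_alpha must lie in [0, 1]")
        if self.maf_shape[0] <= 0 or self.maf_shape[1] <= 0:
            raise ValueError("maf_shape parameters must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.dosage_channels not in ("both", "split"):
            raise ValueError("dosage_channels must be 'both' or 'split'")

    @property
    def n_samples(self) -> int:
        return self.n_control + self.n_ds


def desk_scale_config(
    seed: int = 0,
    dosage_alpha: float = 1.0,
    dosage_channels: DosageChannels = "both",
) -> SyntheticConfig:
    """A reduced cohort preset for CPU-scale experiments.

    200 samples at the study's 1:5 DS:control imbalance (33 DS, 167 control),
    32 genes of 17 SNPs (544 sites), so the default column width of 2 and a
    64-pixel map height give 64x64 chromosome SNP maps. Noise and dosage
    defaults are the study-scale ones.
    """
    return SyntheticConfig(
        n_control=167,
        n_ds=33,
        n_genes=32,
        n_snps=544,
        dosage_alpha=dosage_alpha,
        dosage_channels=dosage_channels,
        seed=seed,
    )


def fusion_benchmark_config(seed: int = 0) -> SyntheticConfig:
    """A cohort built so that fusing the two streams genuinely beats either alone.

    Balanced allele frequencies (Beta(8, 8) clipped to [0.05, 0.5]) make the A
    and B channels each carry half of the expected dosage shift, confounded
    per SNP by the B-allele-count (genotype) noise; the confound cancels only
    in the fused view, because A + B telescopes to gain x copy-number/2
    exactly. One SNP per gene (32 sites) keeps each single channel below its
    classification ceiling at the default noise level, so the two-stream vs
    single-stream comparison is informative rather than saturated. Cohort
    geometry matches :func:`desk_scale_config` (200 samples, 32 genes,
    64x64 maps).
    """
    return SyntheticConfig(
        n_control=167,
        n_ds=33,
        n_genes=32,
        n_snps=32,
        maf_shape=(8.0, 8.0),
        maf_bounds=(0.05, 0.5),
        dosage_channels="both",
        seed=seed,
    )


def make_annotation(cfg: SyntheticConfig) -> SNPAnnotation:
    """Deterministic even SNP-to-gene layout.

    With q = n_snps // n_genes and r = n_snps % n_genes, the first r genes get
    q + 1 SNPs and the remaining genes get q, totalling exactly n_snps. Under
    the study defaults (5458 SNPs, 321 genes) this is one 18-SNP gene and 320
    genes of 17 SNPs.
    """
    q, r = divmod(cfg.n_snps, cfg.n_genes)
    genes = []
    snps_by_gene = []
    snp_counter = 0
    for g in range(cfg.n_genes):
        count = q + 1 if g < r else q
        genes.append(f"GENE{g:04d}")
        snps_by_gene.append(tuple(f"SNP{snp_counter + s:06d}" for s in range(count)))
        snp_counter += count
    return SNPAnnotation(gene_ids=tuple(genes), snp_ids_by_gene=tuple(snps_by_gene))


def normalize_unit_interval(values: np.ndarray) -> np.ndarray:
    """Min-max normalize columns (or a single vector) to [0, 1].

    A constant column maps to all zeros. NaN input is rejected.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot normalize an empty column")
    if np.isnan(values).any():
        raise ValueError("cannot normalize NaN values")
    lo = values.min(axis=0)
    span = values.max(axis=0) - lo
    span_safe = np.where(span > 0, span, 1.0)
    return np.where(span > 0, (values - lo) / span_safe, 0.0)


def simulate_cohort(cfg: SyntheticConfig, normalize: bool = True) -> GenotypeDataset:
    """Simulate a two-channel intensity cohort; fully reproducible from cfg.seed.

    ``normalize=False`` returns the raw (pre min-max) intensities, exposing the
    clean dosage identity: with noise_sd = 0 a trisomic sample's total raw
    intensity A + B equals (2 + alpha)/2 times a control's at every SNP.
    """
    rng = np.random.default_rng(cfg.seed)
    annotation = make_annotation(cfg)
    n, m = cfg.n_samples, cfg.n_snps

    maf = np.clip(rng.beta(*cfg.maf_shape, size=m), *cfg.maf_bounds)
    gain = rng.uniform(*cfg.gain_range, size=m)

    labels = np.array([DS_LABEL] * cfg.n_ds + [CONTROL_LABEL] * cfg.n_control, dtype=object)
    is_ds = labels == DS_LABEL

    # Per-sample copy number and allele draws; alpha = 0 uses the control path
    # exactly so that the null carries no signal at all.
    raw_a = np.empty((n, m))
    raw_b = np.empty((n, m))

    k_control = rng.binomial(2, maf[None, :], size=(n, m)).astype(float)
    k_trisomy = rng.binomial(3, maf[None, :], size=(n, m)).astype(float)

    a_ctrl = gain * (2.0 - k_control) / 2.0
    b_ctrl = gain * k_control / 2.0

    c_eff = 2.0 + cfg.dosage_alpha
    k_eff = k_trisomy * c_eff / 3.0
    a_tri = gain * (c_eff - k_eff) / 2.0
    b_tri = gain * k_eff / 2.0

    trisomic = is_ds[:, None] & (cfg.dosage_alpha > 0)
    if cfg.dosage_channels == "split" and cfg.dosage_alpha > 0:
        # Each SNP's dosage effect lives in one channel only; the other channel
        # keeps the disomic signal for that SNP.
        carries_a = (np.arange(m) % 2 == 0)[None, :]
        raw_a = np.where(trisomic & carries_a, a_tri, a_ctrl)
        raw_b = np.where(trisomic & ~carries_a, b_tri, b_ctrl)
    else:
        raw_a = np.where(trisomic, a_tri, a_ctrl)
        raw_b = np.where(trisomic, b_tri, b_ctrl)

    if cfg.noise_sd > 0:
        raw_a = raw_a + rng.normal(0.0, cfg.noise_sd, size=(n, m))
        raw_b = raw_b + rng.normal(0.0, cfg.noise_sd, size=(n, m))

    order = rng.permutation(n)
    raw_a, raw_b = raw_a[order], raw_b[order]
    if normalize:
        raw_a = normalize_unit_interval(raw_a)
        raw_b = normalize_unit_interval(raw_b)
    return GenotypeDataset(
        sample_ids=[f"S{i:04d}" for i in range(n)],
        labels=labels[order],
        intensities_a=raw_a,
        intensities_b=raw_b,
        annotation=annotation,
    )
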