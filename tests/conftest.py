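import numpy as np
import pytest

from trisomap.io_formats import CONTROL_LABEL, DS_LABEL, GenotypeDataset, SNPAnnotation
from trisomap.synthetic import SyntheticConfig, simulate_cohort


@pytest.fixture
def tiny_annotation() -> SNPAnnotation:
    """Two genes: g1 with three SNPs, g2 with one."""
    return SNPAnnotation(
        gene_ids=("g1", "g2"),
        snp_ids_by_gene=(("s1", "s2", "s3"), ("s4",)),
    )


@pytest.fixture
def tiny_dataset(tiny_annotation) -> GenotypeDataset:
    rng = np.random.default_rng(7)
    n, m = 4, tiny_annotation.n_snps
    return GenotypeDataset(
        sample_ids=[f"P{i}" for i in range(n)],
        labels=np.array([DS_LABEL, CONTROL_LABEL, CONTROL_LABEL, DS_LABEL], dtype=object),
        intensities_a=rng.random((n, m)),
        intensities_b=rng.random((n, m)),
        annotation=tiny_annotation,
    )


@pytest.fixture(scope="session")
def small_cohort() -> GenotypeDataset:
    """A small separable cohort (8 genes, 48 SNPs, 60 samples, 16x16 maps)."""
    cfg = SyntheticConfig(
        n_control=48, n_ds=12, n_genes=8, n_snps=48, dosage_alpha=1.0, seed=11
    )
    return simulate_cohort(cfg)
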