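"""Chromosome SNP maps: grayscale image encoding of per-SNP intensities.

Each gene occupies ``column_width`` adjacent pixel columns (annotation order,
left to right); within a gene, SNP s sits in row s (top-left origin). The
SNP's intensity is replicated across the gene's pixel columns and all pixels
outside the gene/SNP extent hold ``fill_value``. Under the study defaults —
321 genes, column_width 2, height 642 — this yields the 642x642 map geometry.
The encoding is lossless: ``invert_map`` recovers the intensity vector exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import GenotypeDataset, SNPAnnotation


class LayoutError(ValueError):
    """A gene's SNPs do not fit in the configured map height."""


@dataclass(frozen=True)
class MapLayout:
    """Pixel geometry of a chromosome SNP map."""

    column_width: int = 2
    height: int = 642
    fill_value: float = 0.0

    def __post_init__(self) -> None:
        if self.column_width <= 0 or self.height <= 0:
            raise ValueError("column_width and height must be positive")

    def width_for(self, annotation: SNPAnnotation) -> int:
        return annotation.n_genes * self.column_width


@dataclass(frozen=True)
class SNPMapPair:
    """The two chromosome SNP maps for one sample (the two CNN input streams)."""

    map_a: np.ndarray
    map_b: np.ndarray
    sample_id: str
    layout: MapLayout

    def __post_init__(self) -> None:
        if self.map_a.shape != self.map_b.shape:
            raise ValueError("the two maps of a pair must share shape")


def build_map(
    channel_values: np.ndarray, annotation: SNPAnnotation, layout: MapLayout | None = None
) -> np.ndarray:
    """Lay one channel's per-SNP intensities out as a 2D map grid."""
    layout = layout or MapLayout()
    values = np.asarray(channel_values, dtype=float)
    if values.shape != (annotation.n_snps,):
        raise ValueError(
            f"expected {annotation.n_snps} intensities, got shape {values.shape}"
        )
    grid = np.full((layout.height, layout.width_for(annotation)), layout.fill_value, dtype=float)
    offset = 0
    for g, snps in enumerate(annotation.snp_ids_by_gene):
        k = len(snps)
        if k > layout.height:
            raise LayoutError(
                f"gene {annotation.gene_ids[g]} has {k} SNPs but the map height is {layout.height}"
            )
        cols = slice(g * layout.column_width, (g + 1) * layout.column_width)
        grid[:k, cols] = values[offset : offset + k, None]
        offset += k
    return grid


def build_map_pair(
    dataset: GenotypeDataset, sample_index: int, layout: MapLayout | None = None
) -> SNPMapPair:
    """Build both channel maps for one sample of a dataset."""
    layout = layout or MapLayout()
    return SNPMapPair(
        map_a=build_map(dataset.intensities_a[sample_index], dataset.annotation, layout),
        map_b=build_map(dataset.intensities_b[sample_index], dataset.annotation, layout),
        sample_id=dataset.sample_ids[sample_index],
        layout=layout,
    )


def invert_map(
    grid: np.ndarray, annotation: SNPAnnotation, layout: MapLayout | None = None
) -> np.ndarray:
    """Recover the per-SNP intensity vector from a map built with the same layout."""
    layout = layout or MapLayout()
    grid = np.asarray(grid)
    expected = (layout.height, layout.width_for(annotation))
    if grid.shape != expected:
        raise ValueError(f"map shape {grid.shape} does not match layout {expected}")
    values = np.empty(annotation.n_snps, dtype=float)
    offset = 0
    for g, snps in enumerate(annotation.snp_ids_by_gene):
        k = len(snps)
        values[offset : offset + k] = grid[:k, g * layout.column_width]
        offset += k
    return values


def dataset_to_map_stacks(
    dataset: GenotypeDataset, layout: MapLayout | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized map construction for a whole dataset.

    Returns two float32 arrays of shape (n_samples, height, width), one per
    channel, identical sample-by-sample to ``build_map_pair``.
    """
    layout = layout or MapLayout()
    ann = dataset.annotation
    h, w = layout.height, layout.width_for(ann)
    n = dataset.n_samples

    # Precompute the target (row, col-start) of every SNP once.
    rows = np.empty(ann.n_snps, dtype=int)
    gene_idx = np.empty(ann.n_snps, dtype=int)
    offset = 0
    for g, snps in enumerate(ann.snp_ids_by_gene):
        k = len(snps)
        if k > layout.height:
            raise LayoutError(
                f"gene {ann.gene_ids[g]} has {k} SNPs but the map height is {layout.height}"
            )
        rows[offset : offset + k] = np.arange(k)
        gene_idx[offset : offset + k] = g
        offset += k

    stacks = []
    for mat in (dataset.intensities_a, dataset.intensities_b):
        stack = np.full((n, h, w), layout.fill_value, dtype=np.float32)
        for dx in range(layout.column_width):
            stack[:, rows, gene_idx * layout.column_width + dx] = mat
        stacks.append(stack)
    return stacks[0], stacks[1]
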