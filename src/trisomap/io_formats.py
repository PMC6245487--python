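"""On-disk formats for genotype intensity tables, SNP annotation, labels and maps.

All tables are UTF-8, tab-delimited TSV with a header row. The long genotype
layout (``sample_id  snp_id  channel  value``) is canonical; a wide layout with
channel-qualified columns (``<snp_id>:A`` / ``<snp_id>:B``) is supported for
convenience. Chromosome SNP maps and filter weights persist losslessly as
``.npy``; PNG export is 8-bit grayscale and explicitly lossy (visualization
only).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

DS_LABEL = "DS"
CONTROL_LABEL = "control"
CHANNELS = ("A", "B")


class SchemaError(ValueError):
    """A table does not match the expected column schema or annotation."""


class OrderingError(ValueError):
    """Gene/SNP ordering columns contain gaps or duplicates."""


@dataclass(frozen=True)
class SNPAnnotation:
    """Ordered gene list and within-gene SNP ordering; defines the map layout.

    ``gene_ids`` is the total gene order (map columns, left to right);
    ``snp_ids_by_gene[g]`` is the within-gene SNP order (map rows, top down).
    """

    gene_ids: tuple[str, ...]
    snp_ids_by_gene: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        if len(self.gene_ids) != len(self.snp_ids_by_gene):
            raise ValueError("gene_ids and snp_ids_by_gene must align")
        flat = [s for snps in self.snp_ids_by_gene for s in snps]
        if len(set(flat)) != len(flat):
            raise ValueError("duplicate SNP ids in annotation")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_snps(self) -> int:
        return sum(len(s) for s in self.snp_ids_by_gene)

    @property
    def snp_ids(self) -> tuple[str, ...]:
        """All SNP ids in map order (gene-major, then within-gene)."""
        return tuple(s for snps in self.snp_ids_by_gene for s in snps)

    @property
    def max_snps_per_gene(self) -> int:
        return max(len(s) for s in self.snp_ids_by_gene)


@dataclass
class GenotypeDataset:
    """Per-sample, per-SNP two-channel intensities in [0, 1] with labels.

    ``intensities_a``/``intensities_b`` are (n_samples, n_snps) arrays whose
    column order follows ``annotation.snp_ids``.
    """

    sample_ids: list[str]
    labels: np.ndarray  # dtype=object/str, values in {DS, control}
    intensities_a: np.ndarray
    intensities_b: np.ndarray
    annotation: SNPAnnotation = field(repr=False)

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if not (len(self.labels) == n == self.intensities_a.shape[0] == self.intensities_b.shape[0]):
            raise ValueError("sample count mismatch between ids, labels and intensities")
        m = self.annotation.n_snps
        if self.intensities_a.shape[1] != m or self.intensities_b.shape[1] != m:
            raise SchemaError(
                f"intensity column count {self.intensities_a.shape[1]} does not "
                f"match annotation n_snps={m}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return self.annotation.n_snps

    def subset(self, indices: Sequence[int]) -> "GenotypeDataset":
        idx = np.asarray(indices)
        return GenotypeDataset(
            sample_ids=[self.sample_ids[i] for i in idx],
            labels=self.labels[idx],
            intensities_a=self.intensities_a[idx],
            intensities_b=self.intensities_b[idx],
            annotation=self.annotation,
        )

    def features(self, mode: str = "concat") -> np.ndarray:
        """Flat per-sample feature matrix for the classical baselines.

        mode: 'A' | 'B' | 'concat' (A then B columns) | 'sum' (A+B).
        """
        if mode == "A":
            return self.intensities_a
        if mode == "B":
            return self.intensities_b
        if mode == "concat":
            return np.hstack([self.intensities_a, self.intensities_b])
        if mode == "sum":
            return self.intensities_a + self.intensities_b
        raise ValueError(f"unknown feature mode {mode!r}")


# ---------------------------------------------------------------------------
# annotation


def read_annotation(path: str | Path) -> SNPAnnotation:
    """Read a SNP annotation TSV with columns (snp_id, gene_id, gene_order, snp_order).

    Row order is irrelevant: genes are sorted by ``gene_order`` and SNPs within a
    gene by ``snp_order``. Orders must be duplicate-free and gap-free
    (consecutive integers; 0- or 1-based both accepted).
    """
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "gene_id": str})
    required = {"snp_id", "gene_id", "gene_order", "snp_order"}
    if missing := required - set(df.columns):
        raise SchemaError(f"annotation is missing columns {sorted(missing)}")

    gene_orders = df.drop_duplicates("gene_id").set_index("gene_id")["gene_order"]
    _check_consecutive(gene_orders.to_numpy(), what="gene_order")
    genes = gene_orders.sort_values().index.tolist()

    snps_by_gene = []
    for gene in genes:
        sub = df[df["gene_id"] == gene]
        _check_consecutive(sub["snp_order"].to_numpy(), what=f"snp_order in gene {gene}")
        snps_by_gene.append(tuple(sub.sort_values("snp_order")["snp_id"]))
    try:
        return SNPAnnotation(gene_ids=tuple(genes), snp_ids_by_gene=tuple(snps_by_gene))
    except ValueError as exc:
        raise OrderingError(str(exc)) from exc


def _check_consecutive(values: np.ndarray, what: str) -> None:
    vals = np.sort(np.asarray(values, dtype=int))
    if len(np.unique(vals)) != len(vals):
        raise OrderingError(f"duplicate {what} values")
    if len(vals) and not np.array_equal(vals, np.arange(vals[0], vals[0] + len(vals))):
        raise OrderingError(f"gap in {what} values")


def write_annotation(annotation: SNPAnnotation, path: str | Path) -> None:
    rows = []
    for g, gene in enumerate(annotation.gene_ids):
        for s, snp in enumerate(annotation.snp_ids_by_gene[g]):
            rows.append((snp, gene, g, s))
    pd.DataFrame(rows, columns=["snp_id", "gene_id", "gene_order", "snp_order"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# genotype tables


def read_genotype_table(
    path: str | Path,
    annotation: SNPAnnotation,
    labels: dict[str, str] | None = None,
    layout: Literal["long", "wide"] = "long",
    normalized: bool = True,
) -> GenotypeDataset:
    """Read a per-sample, per-SNP two-channel intensity table.

    ``labels`` maps sample id -> class; samples absent from the mapping get
    the control label. With ``normalized=True`` (default) any value outside
    [0, 1] is rejected, naming the offending sample and SNP; ``normalized=False``
    defers normalization to the caller.
    """
    if layout == "long":
        df = pd.read_csv(
            path,
            sep="\t",
            dtype={"sample_id": str, "snp_id": str, "channel": str},
            float_precision="round_trip",
        )
        required = {"sample_id", "snp_id", "channel", "value"}
        if missing := required - set(df.columns):
            raise SchemaError(f"long genotype table is missing columns {sorted(missing)}")
        dup = df.duplicated(["sample_id", "snp_id", "channel"])
        if dup.any():
            first = df[dup].iloc[0]
            raise SchemaError(
                f"duplicate (sample, snp, channel) entry: "
                f"({first['sample_id']}, {first['snp_id']}, {first['channel']})"
            )
        sample_ids = list(dict.fromkeys(df["sample_id"]))
        mats = {}
        for ch in CHANNELS:
            sub = df[df["channel"] == ch].pivot(index="sample_id", columns="snp_id", values="value")
            if missing_snps := set(annotation.snp_ids) - set(sub.columns):
                raise SchemaError(f"missing SNP columns for channel {ch}: {sorted(missing_snps)[:5]}")
            mats[ch] = sub.reindex(index=sample_ids, columns=list(annotation.snp_ids)).to_numpy(float)
    elif layout == "wide":
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, float_precision="round_trip")
        sample_ids = list(df["sample_id"])
        mats = {}
        for ch in CHANNELS:
            cols = [f"{snp}:{ch}" for snp in annotation.snp_ids]
            if missing_cols := set(cols) - set(df.columns):
                raise SchemaError(f"missing wide columns: {sorted(missing_cols)[:5]}")
            mats[ch] = df[cols].to_numpy(float)
    else:
        raise ValueError(f"unknown layout {layout!r}")

    for ch in CHANNELS:
        m = mats[ch]
        if np.isnan(m).any():
            i, j = np.argwhere(np.isnan(m))[0]
            raise SchemaError(
                f"missing value for sample {sample_ids[i]}, SNP {annotation.snp_ids[j]}, channel {ch}"
            )
        if normalized:
            bad = (m < 0.0) | (m > 1.0)
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise SchemaError(
                    f"intensity {m[i, j]} outside [0, 1] for sample {sample_ids[i]}, "
                    f"SNP {annotation.snp_ids[j]}, channel {ch}"
                )

    if labels is None:
        labels = {}
    lab = np.array([labels.get(s, CONTROL_LABEL) for s in sample_ids], dtype=object)
    return GenotypeDataset(sample_ids, lab, mats["A"], mats["B"], annotation)


def write_genotype_table(
    dataset: GenotypeDataset, path: str | Path, layout: Literal["long", "wide"] = "long"
) -> None:
    snps = dataset.annotation.snp_ids
    if layout == "long":
        frames = []
        for ch, mat in (("A", dataset.intensities_a), ("B", dataset.intensities_b)):
            f = pd.DataFrame(mat, columns=list(snps))
            f.insert(0, "sample_id", dataset.sample_ids)
            f = f.melt(id_vars="sample_id", var_name="snp_id", value_name="value")
            f.insert(2, "channel", ch)
            frames.append(f)
        pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False, float_format="%.17g")
    elif layout == "wide":
        data = {"sample_id": dataset.sample_ids}
        for ch, mat in (("A", dataset.intensities_a), ("B", dataset.intensities_b)):
            for j, snp in enumerate(snps):
                data[f"{snp}:{ch}"] = mat[:, j]
        pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.17g")
    else:
        raise ValueError(f"unknown layout {layout!r}")


# ---------------------------------------------------------------------------
# labels


def read_labels(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if missing := {"sample_id", "label"} - set(df.columns):
        raise SchemaError(f"label table is missing columns {sorted(missing)}")
    bad = set(df["label"]) - {DS_LABEL, CONTROL_LABEL}
    if bad:
        raise SchemaError(f"unknown labels {sorted(bad)}; expected {DS_LABEL!r}/{CONTROL_LABEL!r}")
    return dict(zip(df["sample_id"], df["label"]))


def write_labels(sample_ids: Sequence[str], labels: Sequence[str], path: str | Path) -> None:
    pd.DataFrame({"sample_id": list(sample_ids), "label": list(labels)}).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# map images and weight arrays


def write_map_image(
    grid: np.ndarray, path: str | Path, format: Literal["lossless-array", "PNG8"] = "lossless-array"
) -> None:
    """Persist a unit-interval 2D grid.

    ``lossless-array`` round-trips bit-exactly (.npy). ``PNG8`` quantizes to 256
    gray levels via round(value * 255) and is for visualization only.
    """
    grid = np.asarray(grid)
    if grid.ndim != 2:
        raise ValueError("map grid must be 2-dimensional")
    if np.isnan(grid).any():
        raise ValueError("map grid contains NaN pixels")
    if grid.min() < 0.0 or grid.max() > 1.0:
        raise ValueError("map grid values must lie in [0, 1]")
    path = Path(path)
    if format == "lossless-array":
        np.save(path, grid)
    elif format == "PNG8":
        from PIL import Image

        quantized = np.round(grid * 255.0).astype(np.uint8)
        Image.fromarray(quantized, mode="L").save(path, format="PNG")
    else:
        raise ValueError(f"unknown map format {format!r}")


def read_map_image(path: str | Path) -> np.ndarray:
    """Read a lossless-array map (the training path never goes through PNG)."""
    return np.load(Path(path))


# ---------------------------------------------------------------------------
# metric reports


def write_metrics_report(report: dict, path: str | Path) -> None:
    """Serialize a metrics report dict as stable, reproducible JSON."""
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def read_metrics_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
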