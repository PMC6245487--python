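"""Glue between the datasets, the models and the evaluation protocol.

Both the CNNs and the classical baselines run through the identical
``run_protocol`` harness (same seeds -> same train/test splits), differing
only in the fit/predict closure supplied here.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .baselines import BaselineConfig, fit_baseline, predict_baseline
from .evaluation import MetricsReport, run_protocol
from .io_formats import GenotypeDataset
from .model import Arch, BiStreamModelSpec, build_model
from .snpmap import MapLayout, dataset_to_map_stacks


def cnn_protocol(
    dataset: GenotypeDataset,
    spec: BiStreamModelSpec,
    arch: Arch = "bistream",
    layout: MapLayout | None = None,
    n_repeats: int = 10,
    seed: int = 0,
    train_fraction: float = 0.75,
    stratified: bool = False,
) -> MetricsReport:
    """Repeated-split evaluation of a CNN architecture, trained from scratch per run."""
    layout = layout or MapLayout()
    xa, xb = dataset_to_map_stacks(dataset, layout)
    if xa.shape[1:3] != tuple(spec.input_size):
        raise ValueError(
            f"map stack shape {xa.shape[1:3]} does not match spec input {spec.input_size}"
        )

    def fit_predict(train_idx: np.ndarray, test_idx: np.ndarray, run_seed: int) -> np.ndarray:
        net = build_model(arch, replace(spec, seed=run_seed))
        net.fit(xa[train_idx], xb[train_idx], dataset.labels[train_idx])
        return net.predict(xa[test_idx], xb[test_idx])

    return run_protocol(
        fit_predict, dataset.labels, n_repeats, seed, train_fraction, stratified
    )


def baseline_protocol(
    dataset: GenotypeDataset,
    cfg: BaselineConfig,
    n_repeats: int = 10,
    seed: int = 0,
    train_fraction: float = 0.75,
    stratified: bool = False,
) -> MetricsReport:
    """Repeated-split evaluation of a classical baseline on the flat feature table."""
    features = dataset.features(cfg.feature_mode)

    def fit_predict(train_idx: np.ndarray, test_idx: np.ndarray, run_seed: int) -> np.ndarray:
        clf = fit_baseline(
            replace(cfg, seed=run_seed), features[train_idx], dataset.labels[train_idx]
        )
        return predict_baseline(clf, features[test_idx])

    return run_protocol(
        fit_predict, dataset.labels, n_repeats, seed, train_fraction, stratified
    )
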