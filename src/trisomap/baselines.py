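"""Classical-ML baselines on the flat SNP-intensity feature table.

Three classifiers are fitted on per-sample feature vectors (by default the
concatenation of both allele channels, 2 x n_snps columns) under the same
split protocol as the CNNs: C-support-vector classification with the
one-vs-one decision scheme, a random forest (no depth limit, nodes split
while they hold at least 2 samples), and a single CART decision tree (binary
splits maximizing information gain, all features considered at every split).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

Algorithm = Literal["svm", "random_forest", "decision_tree"]


@dataclass
class BaselineConfig:
    """Configuration for one classical baseline."""

    algorithm: Algorithm = "random_forest"
    criterion: Literal["entropy", "gini"] = "entropy"  # forest / tree split quality
    n_estimators: int = 100  # forest size
    svm_c: float = 1.0
    svm_kernel: str = "rbf"
    feature_mode: Literal["A", "B", "concat", "sum"] = "concat"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ("svm", "random_forest", "decision_tree"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")


def make_classifier(cfg: BaselineConfig):
    """Instantiate the configured scikit-learn classifier (unfitted)."""
    if cfg.algorithm == "svm":
        return SVC(
            C=cfg.svm_c,
            kernel=cfg.svm_kernel,
            decision_function_shape="ovo",
            random_state=cfg.seed,
        )
    if cfg.algorithm == "random_forest":
        return RandomForestClassifier(
            n_estimators=cfg.n_estimators,
            criterion=cfg.criterion,
            max_depth=None,
            min_samples_split=2,
            random_state=cfg.seed,
        )
    return DecisionTreeClassifier(
        criterion=cfg.criterion,
        max_depth=None,
        max_features=None,  # all features considered at every split
        random_state=cfg.seed,
    )


def fit_baseline(cfg: BaselineConfig, features: np.ndarray, labels: np.ndarray):
    """Fit the configured classifier; deterministic under cfg.seed."""
    features = np.asarray(features)
    labels = np.asarray(labels)
    if features.shape[0] != len(labels):
        raise ValueError("feature row count must match label count")
    if len(set(labels)) < 2:
        raise ValueError("training set must contain both classes")
    clf = make_classifier(cfg)
    clf.fit(features, labels)
    clf._trisomap_n_features = features.shape[1]
    return clf


def predict_baseline(classifier, features: np.ndarray) -> np.ndarray:
    """Hard labels for new rows; feature width must match training."""
    features = np.asarray(features)
    if features.shape[0] == 0:
        return np.array([], dtype=object)
    expected = getattr(classifier, "_trisomap_n_features", classifier.n_features_in_)
    if features.shape[1] != expected:
        raise ValueError(f"feature width {features.shape[1]} != training width {expected}")
    return classifier.predict(features).astype(object)
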