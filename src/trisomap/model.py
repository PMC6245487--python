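"""Bi-stream CNN for trisomy-21 screening, plus its single-stream ablations.

The bi-stream network takes a sample's two chromosome SNP maps in two
convolutional branches. Each branch: input -> conv C1 (16 filters, 3x3, ReLU)
-> max-pool 2x2 -> dropout 0.25 -> conv C2 -> dropout -> conv C3 -> dropout.
The branches merge by channel concatenation (32 channels) into conv C4 (16
filters), followed by max-pool 2x2, dropout, flatten, a 512-node ReLU dense
layer with dropout, and a 2-node softmax output. Convolutions use same-padding
(spatial size preserved); pooling floors odd sizes, so a 642-pixel map traces
642 -> 321 -> 160 through the two pools. Training uses SGD with learning rate
0.01, decay 1e-6 and Nesterov momentum 0.9 under a softmax cross-entropy loss.

A single-stream ablation keeps one branch and the identical head (its C4 sees
16 input channels instead of 32); it consumes one chromosome SNP map only.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Literal

import numpy as np

from .io_formats import CONTROL_LABEL, DS_LABEL
from .nn import SGD, Conv2D, Dense, Dropout, Flatten, Layer, MaxPool2, softmax, softmax_cross_entropy

#: Output-column order: column 0 = control, column 1 = DS (the positive class).
CLASS_ORDER = (CONTROL_LABEL, DS_LABEL)

Arch = Literal["bistream", "single-a", "single-b"]


@dataclass
class BiStreamModelSpec:
    """Declarative architecture + optimizer description."""

    input_size: tuple[int, int] = (642, 642)
    conv_filters: int = 16
    kernel: tuple[int, int] = (3, 3)
    pool: int = 2
    dropout_rate: float = 0.25
    dense_width: int = 512
    n_classes: int = 2
    learning_rate: float = 0.01
    decay: float = 1e-6
    momentum: float = 0.9
    nesterov: bool = True
    clipnorm: float | None = 5.0
    merge: Literal["concat", "add"] = "concat"
    epochs: int = 50
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.input_size
        if h < 8 or w < 8:
            raise ValueError("input size must be at least 8x8 (two 2x2 pools)")
        if self.conv_filters <= 0 or self.dense_width <= 0:
            raise ValueError("filter count and dense width must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        if self.merge not in ("concat", "add"):
            raise ValueError("merge must be 'concat' or 'add'")


def conv_param_count(filters: int, kernel: tuple[int, int], in_channels: int) -> int:
    """Trainable parameters of a conv layer: filters*(kh*kw*cin) + filters."""
    kh, kw = kernel
    return filters * (kh * kw * in_channels) + filters


def spatial_trace(spec: BiStreamModelSpec) -> list[tuple[int, int]]:
    """(height, width) after: input, branch pool, merge conv, final pool.

    Same-padding convolutions preserve spatial size; each pool floors.
    """
    h, w = spec.input_size
    trace = [(h, w)]
    h, w = h // spec.pool, w // spec.pool
    trace.append((h, w))  # after the branch max-pool (convs preserve size)
    trace.append((h, w))  # after the merge conv (same-padding)
    h, w = h // spec.pool, w // spec.pool
    trace.append((h, w))  # after the final max-pool
    return trace


def _labels_to_onehot(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    unknown = set(labels) - set(CLASS_ORDER)
    if unknown:
        raise ValueError(f"unknown labels {sorted(unknown)}")
    onehot = np.zeros((len(labels), 2), dtype=np.float32)
    onehot[np.arange(len(labels)), (labels == DS_LABEL).astype(int)] = 1.0
    return onehot


class _Network:
    """Shared training/inference machinery for both architectures."""

    spec: BiStreamModelSpec
    layer_registry: dict[str, Conv2D | Dense]
    history: list[float]

    def _forward(self, xa, xb, train: bool, capture: dict | None = None) -> np.ndarray:
        raise NotImplementedError

    def _backward(self, dlogits: np.ndarray) -> None:
        raise NotImplementedError

    def _all_layers(self) -> list[Layer]:
        raise NotImplementedError

    def _params(self):
        return [pg for layer in self._all_layers() for pg in layer.params()]

    @property
    def n_params(self) -> int:
        return sum(p.size for p, _ in self._params())

    def layer_param_counts(self) -> dict[str, int]:
        return {name: layer.n_params for name, layer in self.layer_registry.items()}

    def _check_inputs(self, xa, xb) -> tuple[np.ndarray, np.ndarray]:
        expected = self.spec.input_size
        for x in (xa, xb):
            if x is not None and x.shape[1:3] != expected:
                raise ValueError(f"map shape {x.shape[1:3]} does not match spec input {expected}")
        return xa, xb

    def fit(self, xa: np.ndarray, xb: np.ndarray, labels: np.ndarray) -> "_Network":
        """Train in place; records mean per-epoch loss in ``self.history``."""
        xa, xb = self._check_inputs(xa, xb)
        onehot = _labels_to_onehot(labels)
        if onehot.sum(axis=0).min() == 0:
            raise ValueError("training set must contain both classes")
        n = onehot.shape[0]
        spec = self.spec
        opt = SGD(
            self._params,
            spec.learning_rate,
            spec.decay,
            spec.momentum,
            spec.nesterov,
            spec.clipnorm,
        )
        for _ in range(spec.epochs):
            order = self._rng_train.permutation(n)
            losses = []
            for start in range(0, n, spec.batch_size):
                idx = order[start : start + spec.batch_size]
                logits = self._forward(
                    None if xa is None else xa[idx, :, :, None],
                    None if xb is None else xb[idx, :, :, None],
                    train=True,
                )
                loss, dlogits = softmax_cross_entropy(logits, onehot[idx])
                losses.append(loss * len(idx))
                self._backward(dlogits)
                opt.step()
            self.history.append(sum(losses) / n)
        return self

    def predict_proba(self, xa: np.ndarray, xb: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Class probabilities, columns ordered (control, DS). Deterministic."""
        xa, xb = self._check_inputs(xa, xb)
        n = (xa if xa is not None else xb).shape[0]
        out = np.empty((n, self.spec.n_classes), dtype=np.float32)
        for start in range(0, n, batch_size):
            sl = slice(start, start + batch_size)
            logits = self._forward(
                None if xa is None else xa[sl, :, :, None],
                None if xb is None else xb[sl, :, :, None],
                train=False,
            )
            out[sl] = softmax(logits)
        return out

    def predict(self, xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
        """Hard labels; exact probability ties resolve to control (column 0)."""
        probs = self.predict_proba(xa, xb)
        hard = probs.argmax(axis=1)  # argmax takes the first maximum: control on ties
        return np.array([CLASS_ORDER[i] for i in hard], dtype=object)

    def feature_maps(self, xa: np.ndarray | None, xb: np.ndarray | None, layer: str) -> np.ndarray:
        """Inference-mode activations of a named conv layer, shape (filters, H, W)."""
        if layer not in self.layer_registry or not isinstance(self.layer_registry[layer], Conv2D):
            known = [k for k, v in self.layer_registry.items() if isinstance(v, Conv2D)]
            raise KeyError(f"unknown conv layer {layer!r}; available: {known}")
        capture: dict[str, np.ndarray] = {}
        self._forward(
            None if xa is None else np.asarray(xa, np.float32)[None, :, :, None],
            None if xb is None else np.asarray(xb, np.float32)[None, :, :, None],
            train=False,
            capture=capture,
        )
        return capture[layer][0].transpose(2, 0, 1)

    # -- persistence ------------------------------------------------------

    def save(self, model_dir: str | Path) -> None:
        model_dir = Path(model_dir)
        model_dir.mkdir(parents=True, exist_ok=True)
        meta = {"arch": self.arch, "spec": asdict(self.spec), "history": self.history}
        (model_dir / "model.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
        arrays = {}
        for name, layer in self.layer_registry.items():
            arrays[f"{name}/w"] = layer.w
            arrays[f"{name}/b"] = layer.b
        np.savez(model_dir / "weights.npz", **arrays)

    @staticmethod
    def load(model_dir: str | Path) -> "_Network":
        model_dir = Path(model_dir)
        meta = json.loads((model_dir / "model.json").read_text())
        spec_dict = meta["spec"]
        for key in ("input_size", "kernel"):
            spec_dict[key] = tuple(spec_dict[key])
        spec = BiStreamModelSpec(**spec_dict)
        if meta["arch"] == "bistream":
            net: _Network = build_bistream(spec)
        else:
            net = build_singlestream(spec, stream="A" if meta["arch"] == "single-a" else "B")
        with np.load(model_dir / "weights.npz") as arrays:
            for name, layer in net.layer_registry.items():
                layer.w[...] = arrays[f"{name}/w"]
                layer.b[...] = arrays[f"{name}/b"]
        net.history = list(meta["history"])
        return net


def _run_chain(layers: list[tuple[str, Layer]], x, train, capture):
    for name, layer in layers:
        x = layer.forward(x, train)
        if capture is not None and isinstance(layer, Conv2D):
            capture[name] = x
    return x


class BiStreamNetwork(_Network):
    arch = "bistream"

    def __init__(self, spec: BiStreamModelSpec):
        self.spec = spec
        self.history: list[float] = []
        ss = np.random.SeedSequence(spec.seed)
        init_rng, self._rng_train = (np.random.default_rng(s) for s in ss.spawn(2))
        f, k, d = spec.conv_filters, spec.kernel, spec.dropout_rate

        def branch(tag: str) -> list[tuple[str, Layer]]:
            return [
                (f"C1-{tag}", Conv2D(1, f, k, init_rng, input_layer=True)),
                (f"pool1-{tag}", MaxPool2()),
                (f"drop1-{tag}", Dropout(d, self._rng_train)),
                (f"C2-{tag}", Conv2D(f, f, k, init_rng)),
                (f"drop2-{tag}", Dropout(d, self._rng_train)),
                (f"C3-{tag}", Conv2D(f, f, k, init_rng)),
                (f"drop3-{tag}", Dropout(d, self._rng_train)),
            ]

        self.branch_a = branch("A")
        self.branch_b = branch("B")
        merged_channels = 2 * f if spec.merge == "concat" else f
        h, w = spatial_trace(spec)[-1]
        self.head: list[tuple[str, Layer]] = [
            ("C4", Conv2D(merged_channels, f, k, init_rng)),
            ("pool2", MaxPool2()),
            ("drop4", Dropout(d, self._rng_train)),
            ("flatten", Flatten()),
            ("dense-512", Dense(h * w * f, spec.dense_width, init_rng)),
            ("drop5", Dropout(d, self._rng_train)),
            ("output", Dense(spec.dense_width, spec.n_classes, init_rng, relu=False)),
        ]
        self.layer_registry = {
            name: layer
            for name, layer in self.branch_a + self.branch_b + self.head
            if isinstance(layer, (Conv2D, Dense))
        }

    def _all_layers(self):
        return [layer for _, layer in self.branch_a + self.branch_b + self.head]

    def _forward(self, xa, xb, train, capture=None):
        a = _run_chain(self.branch_a, np.ascontiguousarray(xa, np.float32), train, capture)
        b = _run_chain(self.branch_b, np.ascontiguousarray(xb, np.float32), train, capture)
        merged = np.concatenate([a, b], axis=-1) if self.spec.merge == "concat" else a + b
        self._split = a.shape[-1]
        return _run_chain(self.head, merged, train, capture)

    def _backward(self, dlogits):
        d = dlogits
        for _, layer in reversed(self.head):
            d = layer.backward(d)
        if self.spec.merge == "concat":
            da, db = d[..., : self._split], d[..., self._split :]
        else:
            da = db = d
        for _, layer in reversed(self.branch_a):
            da = layer.backward(da)
        for _, layer in reversed(self.branch_b):
            db = layer.backward(db)


class SingleStreamNetwork(_Network):
    """One-branch ablation; consumes a single chromosome SNP map."""

    def __init__(self, spec: BiStreamModelSpec, stream: Literal["A", "B"] = "A"):
        if stream not in ("A", "B"):
            raise ValueError("stream must be 'A' or 'B'")
        self.spec = spec
        self.stream = stream
        self.arch = f"single-{stream.lower()}"
        self.history: list[float] = []
        ss = np.random.SeedSequence(spec.seed)
        init_rng, self._rng_train = (np.random.default_rng(s) for s in ss.spawn(2))
        f, k, d = spec.conv_filters, spec.kernel, spec.dropout_rate
        h, w = spatial_trace(spec)[-1]
        self.chain: list[tuple[str, Layer]] = [
            (f"C1-{stream}", Conv2D(1, f, k, init_rng, input_layer=True)),
            (f"pool1-{stream}", MaxPool2()),
            (f"drop1-{stream}", Dropout(d, self._rng_train)),
            (f"C2-{stream}", Conv2D(f, f, k, init_rng)),
            (f"drop2-{stream}", Dropout(d, self._rng_train)),
            (f"C3-{stream}", Conv2D(f, f, k, init_rng)),
            (f"drop3-{stream}", Dropout(d, self._rng_train)),
            ("C4", Conv2D(f, f, k, init_rng)),
            ("pool2", MaxPool2()),
            ("drop4", Dropout(d, self._rng_train)),
            ("flatten", Flatten()),
            ("dense-512", Dense(h * w * f, spec.dense_width, init_rng)),
            ("drop5", Dropout(d, self._rng_train)),
            ("output", Dense(spec.dense_width, spec.n_classes, init_rng, relu=False)),
        ]
        self.layer_registry = {
            name: layer for name, layer in self.chain if isinstance(layer, (Conv2D, Dense))
        }

    def _all_layers(self):
        return [layer for _, layer in self.chain]

    def _forward(self, xa, xb, train, capture=None):
        x = xa if self.stream == "A" else xb
        if x is None:
            raise ValueError(f"single-stream {self.stream} model needs channel {self.stream} maps")
        return _run_chain(self.chain, np.ascontiguousarray(x, np.float32), train, capture)

    def _backward(self, dlogits):
        d = dlogits
        for _, layer in reversed(self.chain):
            d = layer.backward(d)


def build_bistream(spec: BiStreamModelSpec) -> BiStreamNetwork:
    return BiStreamNetwork(spec)


def build_singlestream(spec: BiStreamModelSpec, stream: Literal["A", "B"] = "A") -> SingleStreamNetwork:
    return SingleStreamNetwork(spec, stream)


def build_model(arch: Arch, spec: BiStreamModelSpec) -> _Network:
    if arch == "bistream":
        return build_bistream(spec)
    if arch in ("single-a", "single-b"):
        return build_singlestream(spec, stream=arch[-1].upper())
    raise ValueError(f"unknown architecture {arch!r}")
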