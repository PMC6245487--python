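"""Export trained convolutional filters and their feature maps.

Filters are shown as a tiled grayscale montage (each filter min-max scaled
independently for display; a constant filter renders mid-gray); feature maps
are the inference-mode activations of a named convolutional layer for one
sample. Display scaling is non-destructive: the raw weights and activations
are always persisted losslessly alongside any PNG.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .model import _Network
from .nn import Conv2D
from .snpmap import SNPMapPair


def extract_feature_maps(model: _Network, map_pair: SNPMapPair, layer: str) -> np.ndarray:
    """Feature maps (one 2D grid per filter) of a conv layer for one sample.

    Layer names follow the architecture registry: C1-A, C1-B, C2-A, C2-B,
    C3-A, C3-B and the merged C4 (single-stream models expose their own
    branch's names). Dropout is inactive (inference mode).
    """
    return model.feature_maps(map_pair.map_a, map_pair.map_b, layer)


def _scale_tile(tile: np.ndarray) -> np.ndarray:
    span = tile.max() - tile.min()
    if span == 0:
        return np.full_like(tile, 0.5, dtype=float)
    return (tile - tile.min()) / span


def montage(tiles: np.ndarray, n_cols: int | None = None, pad: int = 1) -> np.ndarray:
    """Tile a (n, h, w) stack into one unit-interval grid, row-major.

    Each tile is min-max scaled independently; separators are white (1.0).
    16 tiles default to a 4x4 grid.
    """
    tiles = np.asarray(tiles, dtype=float)
    n, h, w = tiles.shape
    if n_cols is None:
        n_cols = int(np.ceil(np.sqrt(n)))
    n_rows = int(np.ceil(n / n_cols))
    out = np.ones((n_rows * h + (n_rows - 1) * pad, n_cols * w + (n_cols - 1) * pad))
    for i in range(n):
        r, c = divmod(i, n_cols)
        out[r * (h + pad) : r * (h + pad) + h, c * (w + pad) : c * (w + pad) + w] = _scale_tile(
            tiles[i]
        )
    return out


def export_filter_grid(model: _Network, layer: str, path: str | Path) -> np.ndarray:
    """Write a PNG montage of a conv layer's filters; save raw weights losslessly.

    For layers with several input channels the display collapses the kernel to
    its mean over input channels; the lossless ``<path>.weights.npy`` keeps the
    full (kh, kw, in_channels, filters) tensor. Returns the montage grid.
    """
    from .io_formats import write_map_image

    reg = model.layer_registry
    if layer not in reg or not isinstance(reg[layer], Conv2D):
        known = [k for k, v in reg.items() if isinstance(v, Conv2D)]
        raise KeyError(f"unknown conv layer {layer!r}; available: {known}")
    weights = reg[layer].weights_hwcf  # (kh, kw, cin, f)
    path = Path(path)
    np.save(path.with_suffix(path.suffix + ".weights.npy"), weights)
    tiles = weights.mean(axis=2).transpose(2, 0, 1)  # (f, kh, kw)
    grid = montage(tiles)
    write_map_image(grid, path, format="PNG8")
    return grid


def export_feature_map_grid(
    model: _Network, map_pair: SNPMapPair, layer: str, path: str | Path
) -> np.ndarray:
    """Write a PNG montage of a layer's feature maps for one sample; keep raw arrays."""
    from .io_formats import write_map_image

    maps = extract_feature_maps(model, map_pair, layer)
    path = Path(path)
    np.save(path.with_suffix(path.suffix + ".maps.npy"), maps)
    grid = montage(maps)
    write_map_image(grid, path, format="PNG8")
    return grid
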