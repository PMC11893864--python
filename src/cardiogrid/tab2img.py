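"""Tabular-to-image conversion.

A normalized record is laid out on an s x s grid (s = ceil(sqrt(d)); 4 for the
13-feature heart schema) after reordering features so that correlated
features sit adjacently.  The order is the dendrogram leaf order of
average-linkage agglomerative clustering on the distance d = 1 - r derived
from the Pearson correlation matrix of the training data.  Cells beyond the
feature count are zero padding (the last three cells of the fourth row for
d = 13).  The grid is upscaled to a square image (default 224 px) by
nearest-neighbor block replication — no new intensity values are created —
and replicated onto 3 identical channels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .errors import ValidationError


@dataclass(frozen=True)
class FeatureOrder:
    """A permutation of predictor indices plus its provenance."""

    order: tuple
    distance: str = "signed"      # "signed": 1-r ; "absolute": 1-|r|
    linkage_method: str = "average"
    fingerprint: str = ""

    def __post_init__(self) -> None:
        order = tuple(int(i) for i in self.order)
        if sorted(order) != list(range(len(order))):
            raise ValidationError("feature order must be a permutation of 0..d-1")
        object.__setattr__(self, "order", order)

    @property
    def d(self) -> int:
        return len(self.order)

    def inverse(self) -> np.ndarray:
        inv = np.empty(self.d, dtype=int)
        inv[np.asarray(self.order)] = np.arange(self.d)
        return inv


def _correlation_matrix(x: np.ndarray) -> np.ndarray:
    """Pearson correlations; constant columns get correlation 0 with a warning."""
    x = np.asarray(x, dtype=float)
    sd = x.std(axis=0)
    const = sd == 0
    if const.any():
        warnings.warn(f"constant feature(s) at column(s) {np.flatnonzero(const)}; "
                      "correlations set to 0")
    safe = x.copy()
    if const.any():
        # give constants unit variance noise-free placeholder, zero out later
        safe[:, const] = np.arange(len(x))[:, None]
    r = np.corrcoef(safe, rowvar=False)
    r = np.atleast_2d(r)
    r[const, :] = 0.0
    r[:, const] = 0.0
    np.fill_diagonal(r, 1.0)
    return r


def compute_feature_order(train_scaled: np.ndarray, schema=None,
                          distance: str = "signed",
                          linkage_method: str = "average") -> FeatureOrder:
    """Dendrogram leaf order of hierarchical clustering on 1 - correlation."""
    x = np.asarray(train_scaled, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValidationError("need at least 2 rows to compute a feature order")
    d = x.shape[1]
    if d < 1:
        raise ValidationError("need at least 1 feature")
    fp = "" if schema is None else schema.fingerprint()
    if d == 1:
        return FeatureOrder((0,), distance, linkage_method, fp)
    r = _correlation_matrix(x)
    if distance == "signed":
        dist = 1.0 - r
    elif distance == "absolute":
        dist = 1.0 - np.abs(r)
    else:
        raise ValidationError(f"unknown distance transform {distance!r}")
    dist = (dist + dist.T) / 2.0
    # canonicalize away summation-order float noise so ties (e.g. exact
    # duplicate features) break identically regardless of row order
    dist = np.round(dist, 10)
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(np.maximum(dist, 0.0), checks=False)
    z = linkage(condensed, method=linkage_method)
    order = tuple(int(i) for i in leaves_list(z))
    return FeatureOrder(order, distance, linkage_method, fp)


@dataclass
class GridImage:
    """s x s intensity grid for one record, with its padding mask."""

    grid: np.ndarray          # (s, s) floats in [0, 1]
    mask: np.ndarray          # (s, s) bool, True where padded
    order: FeatureOrder

    @property
    def side(self) -> int:
        return self.grid.shape[0]


def grid_side(d: int) -> int:
    return int(math.ceil(math.sqrt(d)))


def embed_grid(record_scaled: np.ndarray, order: FeatureOrder) -> GridImage:
    """Row-major fill of the reordered record; trailing cells zero-padded."""
    v = np.asarray(record_scaled, dtype=float).ravel()
    if v.size != order.d:
        raise ValidationError(f"record length {v.size} != order length {order.d}")
    if np.isnan(v).any() or (v < 0).any() or (v > 1).any():
        raise ValidationError("record values must lie in [0, 1] (normalize first)")
    s = grid_side(order.d)
    flat = np.zeros(s * s, dtype=float)
    flat[: order.d] = v[np.asarray(order.order)]
    mask = np.ones(s * s, dtype=bool)
    mask[: order.d] = False
    return GridImage(flat.reshape(s, s), mask.reshape(s, s), order)


def recover_record(image: GridImage) -> np.ndarray:
    """Invert :func:`embed_grid` exactly: grid + order + mask -> scaled record."""
    flat = image.grid.ravel()[~image.mask.ravel()]
    return flat[image.order.inverse()]


def _upscale_grid(grid: np.ndarray, target_side: int) -> np.ndarray:
    s = grid.shape[-1]
    if target_side < s:
        raise ValidationError(f"target side {target_side} < grid side {s}")
    idx = (np.arange(target_side) * s) // target_side
    return grid[..., idx, :][..., :, idx]


def upscale(image, target_side: int = 224) -> np.ndarray:
    """Nearest-neighbor block replication to (S, S, 3); intensities preserved."""
    grid = image.grid if isinstance(image, GridImage) else np.asarray(image)
    up = _upscale_grid(grid, target_side)
    return np.repeat(up[..., None], 3, axis=-1)


def convert_dataset(ds_scaled: np.ndarray, order: FeatureOrder,
                    target_side: int = 224) -> np.ndarray:
    """Whole-matrix conversion: (n, d) scaled values -> (n, S, S, 3) stack."""
    x = np.asarray(ds_scaled, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[1] != order.d:
        raise ValidationError("column count does not match feature order")
    if np.isnan(x).any() or (x < 0).any() or (x > 1).any():
        raise ValidationError("values must lie in [0, 1] (normalize first)")
    s = grid_side(order.d)
    flat = np.zeros((x.shape[0], s * s), dtype=float)
    flat[:, : order.d] = x[:, np.asarray(order.order)]
    grids = flat.reshape(-1, s, s)
    up = _upscale_grid(grids, target_side)
    return np.repeat(up[..., None], 3, axis=-1)


def export_png(image, path, target_side: Optional[int] = None) -> None:
    """8-bit grayscale PNG of a grid (value = round(255 * intensity))."""
    from PIL import Image as PILImage

    grid = image.grid if isinstance(image, GridImage) else np.asarray(image)
    if target_side is not None:
        grid = _upscale_grid(grid, target_side)
    arr = np.round(255.0 * grid).astype(np.uint8)
    PILImage.fromarray(arr, mode="L").save(path)
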