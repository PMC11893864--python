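"""Frozen convolutional backbones for deep feature extraction.

Two backends share one contract: a backbone is created once, its weights are
frozen forever, and :func:`extract_features` is a pure function of
(weights, image stack).

* ``toy`` — a seeded random stack (grayscale pooling, one bank of bias-free
  3x3 convolutions, ReLU, global spatial average pooling, random linear
  projection).  Deterministic, dependency-free, bit-reproducible; the default
  for tests and desk-scale runs.
* ``vgg16`` — adapter around the pretrained ImageNet network; emits 512
  features under global average pooling of the final convolutional layer.
  Requires its optional deep-learning dependency; when that is absent a
  :class:`CapabilityError` points at the toy backend.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import CapabilityError, ValidationError


@dataclass(frozen=True)
class BackboneSpec:
    backend: str                      # "toy" | "vgg16"
    input_side: int = 224
    output_dim: int = 32
    pooling: str = "avg"              # "avg" | "flatten" (vgg16 only)
    seed: Optional[int] = None        # toy only
    frozen: bool = True

    def __post_init__(self) -> None:
        if self.backend not in ("toy", "vgg16"):
            raise ValidationError(f"unknown backbone backend {self.backend!r}")
        if self.output_dim < 1:
            raise ValidationError("output_dim must be >= 1")
        if not self.frozen:
            raise ValidationError("backbones are frozen by contract")


@dataclass
class ToyBackbone:
    """Seeded random frozen feature extractor; rejects any training call."""

    spec: BackboneSpec
    conv: np.ndarray = field(repr=False)       # (9, n_filters), bias-free
    proj: np.ndarray = field(repr=False)       # (n_filters, output_dim)
    pool_side: int = 28

    def fit(self, *args, **kwargs):  # pragma: no cover - contract guard
        raise CapabilityError("backbone is frozen; no training path exists")

    def extract(self, images: np.ndarray) -> np.ndarray:
        return _toy_forward(self, images)

    def to_dict(self) -> dict:
        return {"spec": self.spec.__dict__.copy(), "conv": self.conv,
                "proj": self.proj, "pool_side": self.pool_side}

    @classmethod
    def from_dict(cls, d: dict) -> "ToyBackbone":
        return cls(BackboneSpec(**d["spec"]), d["conv"], d["proj"], d["pool_side"])


def make_toy_backbone(seed: int, output_dim: int = 32, input_side: int = 224,
                      n_filters: int = 16, pool_side: int = 28) -> ToyBackbone:
    """Create a frozen toy backbone; different seeds give different weights."""
    if output_dim < 1:
        raise ValidationError("output_dim must be >= 1")
    rng = np.random.default_rng(seed)
    conv = rng.standard_normal((9, n_filters)) / 3.0
    proj = rng.standard_normal((n_filters, output_dim)) / np.sqrt(n_filters)
    spec = BackboneSpec("toy", input_side=input_side, output_dim=output_dim,
                        pooling="avg", seed=int(seed))
    return ToyBackbone(spec, conv, proj, pool_side=min(pool_side, input_side))


def _pool_matrix(src: int, dst: int) -> np.ndarray:
    """(dst, src) row-stochastic binned-average pooling operator."""
    bins = (np.arange(src) * dst) // src
    m = np.zeros((dst, src))
    m[bins, np.arange(src)] = 1.0
    return m / m.sum(axis=1, keepdims=True)


def _toy_forward(bb: ToyBackbone, images: np.ndarray) -> np.ndarray:
    x = np.asarray(images, dtype=float)
    if x.ndim == 3:
        x = x[None, ...]
    n, s0, s1, c = x.shape
    gray = x.mean(axis=-1)
    p = bb.pool_side
    if p < s0:
        m = _pool_matrix(s0, p)
        gray = np.einsum("ps,nst->npt", m, gray)
        gray = np.einsum("qt,npt->npq", m, gray)
        side = p
    else:
        side = s0
    if side < 3:
        raise ValidationError("pooled image too small for 3x3 convolution")
    # im2col: (n, (side-2)^2, 9)
    win = np.lib.stride_tricks.sliding_window_view(gray, (3, 3), axis=(1, 2))
    patches = win.reshape(n, -1, 9)
    act = np.maximum(patches @ bb.conv, 0.0)      # ReLU, no bias
    pooled = act.mean(axis=1)                     # global spatial average
    return pooled @ bb.proj                       # seeded linear projection


class Vgg16Backbone:
    """Adapter around the pretrained network (optional dependency)."""

    def __init__(self, pooling: str = "avg"):
        try:  # pragma: no cover - exercised only when tensorflow is installed
            from tensorflow.keras.applications import vgg16 as _vgg16  # noqa: F401
        except Exception as exc:
            raise CapabilityError(
                "the vgg16 backend needs its optional deep-learning dependency "
                "(pip install cardiogrid[vgg16]); use the toy backend instead"
            ) from exc
        from tensorflow.keras.applications import VGG16  # pragma: no cover
        self._pre = _vgg16.preprocess_input  # pragma: no cover
        pool = "avg" if pooling == "avg" else None  # pragma: no cover
        self._model = VGG16(weights="imagenet", include_top=False,  # pragma: no cover
                            pooling=pool)
        dim = 512 if pooling == "avg" else 25088  # pragma: no cover
        self.spec = BackboneSpec("vgg16", input_side=224,  # pragma: no cover
                                 output_dim=dim, pooling=pooling)

    def extract(self, images: np.ndarray) -> np.ndarray:  # pragma: no cover
        # backbone-specific preprocessing (0-255 rescale + mean shift) lives here
        x = self._pre(np.asarray(images, dtype=float) * 255.0)
        out = self._model.predict(x, verbose=0)
        return out.reshape(out.shape[0], -1)


def make_backbone(spec: BackboneSpec):
    if spec.backend == "toy":
        return make_toy_backbone(spec.seed if spec.seed is not None else 0,
                                 output_dim=spec.output_dim,
                                 input_side=spec.input_side)
    return Vgg16Backbone(pooling=spec.pooling)


def extract_features(images: np.ndarray, backbone) -> np.ndarray:
    """Apply a frozen backbone to an (n, S, S, 3) stack -> (n, d_cnn) matrix."""
    x = np.asarray(images, dtype=float)
    if x.ndim == 3:
        x = x[None, ...]
    side = backbone.spec.input_side
    if x.shape[1] != side or x.shape[2] != side:
        raise ValidationError(
            f"image side {x.shape[1]}x{x.shape[2]} does not match backbone "
            f"expected side {side}")
    return backbone.extract(x)
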