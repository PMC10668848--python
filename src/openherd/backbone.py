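"""Feature-extractor contract f(x) and a small trainable convolutional net.

The open-set machinery (margin softmax head, reciprocal points, metrics) is
agnostic to how features are produced: anything that maps an image batch to
an ``(n, embed_dim)`` array and exposes parameters/gradients satisfies the
contract, including wrappers around externally pretrained extractors.  The
default implementation is a deliberately small from-scratch conv net — four
conv/ReLU/pool blocks followed by global average pooling and a linear
projection — sized for CPU experimentation on the synthetic herd.

All layers carry hand-written backward passes; gradients are verified
against central finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["FeatureExtractorSpec", "SmallConvNet", "build_extractor", "embed",
           "register_extractor"]


@dataclass(frozen=True)
class FeatureExtractorSpec:
    """Architecture-level description of a feature extractor.

    ``embed_dim`` is the dimension of f(x); ``architecture`` selects a
    registered factory; ``pretrained`` optionally locates external weights
    understood by that factory (the default net ignores it).
    """

    input_size: int = 64
    embed_dim: int = 128
    architecture: str = "smallconv"
    channels: tuple[int, ...] = (8, 16, 32, 64)
    embed_norm: float | None = 8.0
    pretrained: str | None = None

    def __post_init__(self) -> None:
        if self.embed_dim < 2:
            raise ValueError(f"embed_dim must be >= 2, got {self.embed_dim}")
        if self.input_size < 16:
            raise ValueError(f"input_size must be >= 16, got {self.input_size}")
        if self.embed_norm is not None and self.embed_norm <= 0:
            raise ValueError("embed_norm must be positive (or None to disable)")


class _Layer:
    params: dict[str, np.ndarray]
    grads: dict[str, np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = {}, {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Conv3x3(_Layer):
    """3x3 same-padding convolution, implemented as nine shifted tensordots."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        fan_in = c_in * 9
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, c_in, 3, 3))
        self.params["b"] = np.zeros(c_out)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        self._xpad = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        W = self.params["W"]
        out = np.zeros((n, W.shape[0], h, w))
        for di in range(3):
            for dj in range(3):
                patch = self._xpad[:, :, di:di + h, dj:dj + w]
                out += np.tensordot(patch, W[:, :, di, dj], axes=([1], [1])).transpose(0, 3, 1, 2)
        out += self.params["b"][None, :, None, None]
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c_out, h, w = dout.shape
        W = self.params["W"]
        dW = np.zeros_like(W)
        dxpad = np.zeros_like(self._xpad)
        for di in range(3):
            for dj in range(3):
                patch = self._xpad[:, :, di:di + h, dj:dj + w]
                dW[:, :, di, dj] = np.tensordot(dout, patch, axes=([0, 2, 3], [0, 2, 3]))
                dxpad[:, :, di:di + h, dj:dj + w] += np.tensordot(
                    dout, W[:, :, di, dj], axes=([1], [0])
                ).transpose(0, 3, 1, 2)
        self.grads["W"] = dW
        self.grads["b"] = dout.sum(axis=(0, 2, 3))
        return dxpad[:, :, 1:-1, 1:-1]


class ReLU(_Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class AvgPool2(_Layer):
    """2x2 average pooling; trailing odd rows/cols are dropped."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        self._in_shape = x.shape
        h2, w2 = h // 2, w // 2
        x = x[:, :, : h2 * 2, : w2 * 2]
        return x.reshape(n, c, h2, 2, w2, 2).mean(axis=(3, 5))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        dx = np.zeros(self._in_shape)
        up = np.repeat(np.repeat(dout, 2, axis=2), 2, axis=3) / 4.0
        dx[:, :, : up.shape[2], : up.shape[3]] = up
        return dx


class GlobalAvgPool(_Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        return np.broadcast_to(dout[:, :, None, None], self._in_shape) / (h * w)


class Dense(_Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params["W"] = rng.normal(0.0, np.sqrt(2.0 / d_in), (d_in, d_out))
        self.params["b"] = np.zeros(d_out)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class ScaledUnitNorm(_Layer):
    """Constrain the embedding to a hypersphere: ``f = rho * g / ||g||``.

    Keeping the embedding norm fixed makes distance-based open-set scores a
    clean function of direction rather than of per-sample norm fluctuations
    (the standard convention in margin-softmax face embeddings).
    """

    def __init__(self, rho: float) -> None:
        super().__init__()
        self.rho = float(rho)

    def forward(self, g: np.ndarray) -> np.ndarray:
        self._n = np.sqrt(np.sum(g * g, axis=1, keepdims=True)) + 1e-12
        self._gn = g / self._n
        return self.rho * self._gn

    def backward(self, dout: np.ndarray) -> np.ndarray:
        gn = self._gn
        return self.rho * (dout - gn * np.sum(gn * dout, axis=1, keepdims=True)) / self._n


class SmallConvNet:
    """Four conv blocks (conv -> ReLU -> avgpool) -> GAP -> linear embedding.

    With ``spec.embed_norm`` set (the default) the embedding is projected to
    a sphere of that radius by :class:`ScaledUnitNorm`.
    """

    def __init__(self, spec: FeatureExtractorSpec, seed: int = 0, in_channels: int = 1) -> None:
        self.spec = spec
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xBB]))
        self.layers: list[_Layer] = []
        c_prev = in_channels
        for c in spec.channels:
            self.layers += [Conv3x3(c_prev, c, rng), ReLU(), AvgPool2()]
            c_prev = c
        self.layers += [GlobalAvgPool(), Dense(c_prev, spec.embed_dim, rng)]
        if spec.embed_norm is not None:
            self.layers.append(ScaledUnitNorm(spec.embed_norm))

    def forward(self, images: np.ndarray, train: bool = False) -> np.ndarray:
        x = _to_nchw(images, self.spec.input_size)
        for layer in self.layers:
            x = layer.forward(x)
        return x

    __call__ = forward

    def backward(self, dfeatures: np.ndarray) -> None:
        d = dfeatures
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def parameters(self) -> list[tuple[str, _Layer, str]]:
        out = []
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                out.append((f"layer{i}.{name}", layer, name))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {key: layer.params[name].copy() for key, layer, name in self.parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for key, layer, name in self.parameters():
            if key not in state:
                raise KeyError(f"missing parameter {key} in checkpoint")
            if state[key].shape != layer.params[name].shape:
                raise ValueError(f"shape mismatch for {key}")
            layer.params[name] = state[key].copy()


def _to_nchw(images: np.ndarray, input_size: int) -> np.ndarray:
    """Accept (n, H, W), (n, H, W, 3) or (n, C, H, W); validate spatial size."""
    x = np.asarray(images, dtype=float)
    if x.ndim == 3:
        x = x[:, None, :, :]
    elif x.ndim == 4 and x.shape[-1] in (1, 3) and x.shape[1] not in (1, 3):
        x = x.transpose(0, 3, 1, 2)
    elif x.ndim != 4:
        raise ValueError(f"expected an image batch, got array of shape {x.shape}")
    if x.shape[2] != input_size or x.shape[3] != input_size:
        raise ValueError(
            f"images are {x.shape[2]}x{x.shape[3]} but the extractor expects "
            f"{input_size}x{input_size}"
        )
    return x


_REGISTRY: dict[str, Callable[[FeatureExtractorSpec, int], object]] = {}


def register_extractor(name: str, factory: Callable[[FeatureExtractorSpec, int], object]) -> None:
    """Register a factory for an ``architecture`` tag.

    The factory receives ``(spec, seed)`` and must return an object with
    ``forward(images, train=False)``; this is the hook through which
    externally pretrained extractors (e.g. a ResNet or ViT wrapper) plug into
    training and evaluation unchanged.
    """
    _REGISTRY[name] = factory


register_extractor("smallconv", lambda spec, seed: SmallConvNet(spec, seed=seed))


def build_extractor(spec: FeatureExtractorSpec, seed: int = 0):
    """Instantiate the extractor named by ``spec.architecture``."""
    if spec.architecture not in _REGISTRY:
        raise ValueError(
            f"unknown architecture {spec.architecture!r}; registered: {sorted(_REGISTRY)}"
        )
    return _REGISTRY[spec.architecture](spec, seed)


def embed(images: np.ndarray, spec: FeatureExtractorSpec, extractor) -> np.ndarray:
    """Evaluate f(x) for a batch: returns an ``(n, embed_dim)`` float array."""
    feats = np.asarray(extractor.forward(images, train=False))
    if feats.ndim != 2 or feats.shape[1] != spec.embed_dim:
        raise ValueError(
            f"extractor returned shape {feats.shape}, expected (n, {spec.embed_dim})"
        )
    if not np.all(np.isfinite(feats)):
        raise ValueError("extractor produced non-finite features")
    return feats
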