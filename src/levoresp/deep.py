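"""Fixed 3D convolutional backbone used as a pure feature extractor.

The default backbone is a 3D residual network in the configuration used for
medical-image segmentation encoders: 7^3 stem convolution with stride 2, a
stride-2 max pool, four basic-block stages ending at 512 channels, with the
last two stages dilated (2 and 4) instead of strided so the overall spatial
output stride is 8. The segmentation head is replaced by a max-pooling layer
(kernel 8, stride 8, padding 0) and a flattening layer; for a 193 x 229 x 193
input this yields a 3 x 3 x 3 x 512 pooled map = 13,824 features. Block
depth (10/18/34) is configurable and does not change the output size.

Everything is plain numpy: convolutions are im2col + BLAS matmuls in float32,
chunked so peak memory stays modest. The network is inference-only; weights
are either seeded random (He) initialization or loaded from an ``.npz``
bundle. A ``tiny-cnn`` profile (3 conv stages, output stride 4, pool 2)
serves desk-scale volumes.

Feature i of the flattened output corresponds to position
``unravel_index(i, (C, X, Y, Z))`` of the pooled map (channel-major,
row-major); names are ``ResNet_<i>``. The forward pass caches the last
convolutional activation and the pool argmax indices so saliency can
backpropagate a gradient seed through the head exactly.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from .grids import VolumeGrid

__all__ = [
    "ExtractorConfig",
    "DeepExtractor",
    "build_extractor",
    "output_dim",
    "feature_to_coords",
    "coords_to_feature",
]

_CHUNK_FLOATS = 3 * 10**7  # im2col buffer bound (~120 MB in float32)

_DEPTH_BLOCKS = {10: (1, 1, 1, 1), 18: (2, 2, 2, 2), 34: (3, 4, 6, 3)}


def _conv_out(n: int, k: int, s: int, p: int, d: int = 1) -> int:
    return (n + 2 * p - d * (k - 1) - 1) // s + 1


def conv3d(
    x: np.ndarray, w: np.ndarray, stride: int = 1, pad: int = 0, dilation: int = 1
) -> np.ndarray:
    """3D convolution, x (C, X, Y, Z) by w (O, C, k, k, k), via chunked im2col."""
    O, C, k = w.shape[0], w.shape[1], w.shape[2]
    span = dilation * (k - 1) + 1
    xp = np.pad(x, ((0, 0),) + ((pad, pad),) * 3) if pad else x
    v = sliding_window_view(xp, (span, span, span), axis=(1, 2, 3))
    v = v[:, ::stride, ::stride, ::stride, ::dilation, ::dilation, ::dilation]
    _, Ox, Oy, Oz = v.shape[:4]
    W2 = np.ascontiguousarray(w.reshape(O, -1).T, dtype=np.float32)  # (C*k^3, O)
    out = np.empty((O, Ox, Oy, Oz), dtype=np.float32)
    per_slab = max(C * k**3 * Oy * Oz, 1)
    step = max(1, _CHUNK_FLOATS // per_slab)
    for s0 in range(0, Ox, step):
        s1 = min(Ox, s0 + step)
        patch = (
            v[:, s0:s1]
            .transpose(1, 2, 3, 0, 4, 5, 6)
            .reshape((s1 - s0) * Oy * Oz, -1)
            .astype(np.float32, copy=False)
        )
        out[:, s0:s1] = (patch @ W2).T.reshape(O, s1 - s0, Oy, Oz)
    return out


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0, out=x)


def _bn(x: np.ndarray, gamma: np.ndarray, beta: np.ndarray) -> np.ndarray:
    return x * gamma[:, None, None, None] + beta[:, None, None, None]


def _maxpool_s2(x: np.ndarray) -> np.ndarray:
    """Max pool kernel 3, stride 2, padding 1 over the spatial axes."""
    filt = ndimage.maximum_filter(
        x, size=(1, 3, 3, 3), mode="constant", cval=-np.inf
    )
    return filt[:, ::2, ::2, ::2]


def head_pool(x: np.ndarray, kernel: int, stride: int, padding: int = 0):
    """Non-overlapping head max pool (kernel == stride, padding 0).

    Returns (pooled, argmax) where argmax holds, per pooled cell, the flat
    index within its kernel block -- enough to route gradients back exactly.
    """
    if padding != 0 or kernel != stride:
        raise ValueError("head pool supports kernel == stride, padding 0 only")
    C = x.shape[0]
    dims = [(n - kernel) // stride + 1 for n in x.shape[1:]]
    if min(dims) < 1:
        raise ValueError(
            f"feature map {x.shape[1:]} smaller than pool kernel {kernel}"
        )
    ox, oy, oz = dims
    crop = x[:, : ox * kernel, : oy * kernel, : oz * kernel]
    blocks = crop.reshape(C, ox, kernel, oy, kernel, oz, kernel)
    blocks = blocks.transpose(0, 1, 3, 5, 2, 4, 6).reshape(C, ox, oy, oz, kernel**3)
    arg = blocks.argmax(axis=-1)
    pooled = np.take_along_axis(blocks, arg[..., None], axis=-1)[..., 0]
    return pooled, arg


def head_pool_backward(
    grad: np.ndarray, arg: np.ndarray, kernel: int, conv_shape: tuple[int, ...]
) -> np.ndarray:
    """Scatter a pooled-map gradient back to the last-conv grid."""
    C, ox, oy, oz = grad.shape
    out = np.zeros((C, ox, oy, oz, kernel**3), dtype=np.float64)
    np.put_along_axis(out, arg[..., None], grad[..., None], axis=-1)
    out = out.reshape(C, ox, oy, oz, kernel, kernel, kernel)
    out = out.transpose(0, 1, 4, 2, 5, 3, 6).reshape(
        C, ox * kernel, oy * kernel, oz * kernel
    )
    full = np.zeros(conv_shape, dtype=np.float64)
    full[:, : ox * kernel, : oy * kernel, : oz * kernel] = out
    return full


@dataclass
class ExtractorConfig:
    backbone: str = "resnet3d-512ch"  # or "tiny-cnn"
    depth: int = 10  # resnet block depth: 10, 18 or 34
    pool_kernel: int | None = None  # None -> backbone default (8 resnet, 2 tiny)
    pool_stride: int | None = None
    pool_padding: int = 0
    weights_path: str | None = None
    seed: int = 0
    input_shape: tuple[int, int, int] | None = None
    name_prefix: str = "ResNet"

    def __post_init__(self) -> None:
        if self.backbone not in ("resnet3d-512ch", "tiny-cnn"):
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if self.backbone == "resnet3d-512ch" and self.depth not in _DEPTH_BLOCKS:
            raise ValueError(f"resnet depth must be one of {sorted(_DEPTH_BLOCKS)}")
        default = 8 if self.backbone == "resnet3d-512ch" else 2
        if self.pool_kernel is None:
            self.pool_kernel = default
        if self.pool_stride is None:
            self.pool_stride = self.pool_kernel


def _layer_specs(config: ExtractorConfig) -> list[dict]:
    """Flat conv-layer plan; each entry describes one weight tensor."""
    specs: list[dict] = []
    if config.backbone == "tiny-cnn":
        chans = [(1, 16, 2), (16, 32, 2), (32, 16, 1)]
        for li, (ci, co, s) in enumerate(chans):
            specs.append(dict(name=f"conv{li}", cin=ci, cout=co, k=3, stride=s, pad=1, dil=1))
        return specs
    specs.append(dict(name="stem", cin=1, cout=64, k=7, stride=2, pad=3, dil=1))
    blocks = _DEPTH_BLOCKS[config.depth]
    cin = 64
    stage_params = [(64, 1, 1), (128, 2, 1), (256, 1, 2), (512, 1, 4)]
    for si, ((cout, stride, dil), nb) in enumerate(zip(stage_params, blocks)):
        for bi in range(nb):
            s = stride if bi == 0 else 1
            base = f"layer{si + 1}.{bi}"
            specs.append(dict(name=f"{base}.conv1", cin=cin, cout=cout, k=3, stride=s, pad=dil, dil=dil))
            specs.append(dict(name=f"{base}.conv2", cin=cout, cout=cout, k=3, stride=1, pad=dil, dil=dil))
            if s != 1 or cin != cout:
                specs.append(dict(name=f"{base}.down", cin=cin, cout=cout, k=1, stride=s, pad=0, dil=1))
            cin = cout
    return specs


def backbone_map_shape(config: ExtractorConfig, input_shape: tuple[int, int, int]):
    """(channels, spatial shape) of the last convolutional feature map."""
    dims = list(input_shape)
    if config.backbone == "tiny-cnn":
        for s in (2, 2, 1):
            dims = [_conv_out(n, 3, s, 1) for n in dims]
        return 16, tuple(dims)
    dims = [_conv_out(n, 7, 2, 3) for n in dims]  # stem
    dims = [_conv_out(n, 3, 2, 1) for n in dims]  # stride-2 max pool
    dims = [_conv_out(n, 3, 2, 1) for n in dims]  # stage 2 downsampling
    return 512, tuple(dims)  # dilated stages 3-4 preserve size


def pooled_shape(config: ExtractorConfig, input_shape: tuple[int, int, int]):
    ch, dims = backbone_map_shape(config, input_shape)
    k, s = config.pool_kernel, config.pool_stride
    out = tuple((n - k) // s + 1 for n in dims)
    if min(out) < 1:
        raise ValueError(
            f"feature map {dims} too small for pool kernel {k} (input {input_shape})"
        )
    return (ch,) + out


def output_dim(config: ExtractorConfig, input_shape: tuple[int, int, int]) -> int:
    """Closed-form output length: channels x prod(floor((m - k)/s) + 1)."""
    return int(np.prod(pooled_shape(config, input_shape)))


def feature_to_coords(flat_index: int, pooled: tuple[int, int, int, int]):
    """Inverse of the channel-major, row-major flatten."""
    n = int(np.prod(pooled))
    if not 0 <= flat_index < n:
        raise IndexError(f"feature index {flat_index} outside [0, {n})")
    return tuple(int(c) for c in np.unravel_index(flat_index, pooled))


def coords_to_feature(coords: tuple[int, int, int, int], pooled) -> int:
    return int(np.ravel_multi_index(coords, pooled))


class DeepExtractor:
    """Inference-only feature extractor; parameters are fixed at build time."""

    def __init__(self, config: ExtractorConfig):
        self.config = config
        self.specs = _layer_specs(config)
        if config.weights_path is not None:
            self.weights = self._load_weights(config.weights_path)
        else:
            self.weights = self._init_weights(config.seed)

    # -- parameters ---------------------------------------------------------
    def _param_shapes(self) -> dict[str, tuple]:
        shapes: dict[str, tuple] = {}
        for sp in self.specs:
            shapes[f"{sp['name']}.w"] = (sp["cout"], sp["cin"], sp["k"], sp["k"], sp["k"])
            shapes[f"{sp['name']}.g"] = (sp["cout"],)
            shapes[f"{sp['name']}.b"] = (sp["cout"],)
        return shapes

    def _init_weights(self, seed: int) -> dict[str, np.ndarray]:
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(99,)))
        weights: dict[str, np.ndarray] = {}
        for name, shape in self._param_shapes().items():
            if name.endswith(".w"):
                fan_in = int(np.prod(shape[1:]))
                weights[name] = rng.normal(0.0, np.sqrt(2.0 / fan_in), shape).astype(np.float32)
            elif name.endswith(".g"):
                weights[name] = np.ones(shape, dtype=np.float32)
            else:
                weights[name] = np.zeros(shape, dtype=np.float32)
        return weights

    def _load_weights(self, path: str) -> dict[str, np.ndarray]:
        with np.load(path) as npz:
            loaded = {k: npz[k] for k in npz.files}
        expected = self._param_shapes()
        missing = sorted(set(expected) - set(loaded))
        if missing:
            raise ValueError(f"weights file {path} missing parameters: {missing[:5]}")
        for name, shape in expected.items():
            if loaded[name].shape != shape:
                raise ValueError(
                    f"weights/backbone mismatch for {name}: file has "
                    f"{loaded[name].shape}, architecture needs {shape}"
                )
        return {k: loaded[k].astype(np.float32) for k in expected}

    def save_weights(self, path: str | Path) -> None:
        np.savez(path, **self.weights)

    # -- forward ------------------------------------------------------------
    def _conv_unit(self, x: np.ndarray, name: str, sp: dict) -> np.ndarray:
        y = conv3d(x, self.weights[f"{name}.w"], sp["stride"], sp["pad"], sp["dil"])
        return _bn(y, self.weights[f"{name}.g"], self.weights[f"{name}.b"])

    def _backbone(self, x: np.ndarray) -> np.ndarray:
        spec_by_name = {sp["name"]: sp for sp in self.specs}
        if self.config.backbone == "tiny-cnn":
            for li in range(3):
                x = _relu(self._conv_unit(x, f"conv{li}", spec_by_name[f"conv{li}"]))
            return x
        x = _relu(self._conv_unit(x, "stem", spec_by_name["stem"]))
        x = _maxpool_s2(x)
        blocks = _DEPTH_BLOCKS[self.config.depth]
        for si, nb in enumerate(blocks):
            for bi in range(nb):
                base = f"layer{si + 1}.{bi}"
                idn = x
                y = _relu(self._conv_unit(x, f"{base}.conv1", spec_by_name[f"{base}.conv1"]))
                y = self._conv_unit(y, f"{base}.conv2", spec_by_name[f"{base}.conv2"])
                if f"{base}.down" in spec_by_name:
                    idn = self._conv_unit(x, f"{base}.down", spec_by_name[f"{base}.down"])
                x = _relu(y + idn)
        return x

    @staticmethod
    def _normalize(vol: np.ndarray) -> np.ndarray:
        sd = vol.std()
        if sd > 0:
            vol = (vol - vol.mean()) / sd
        return vol.astype(np.float32)

    def forward(self, v: VolumeGrid | np.ndarray):
        """Run the network; returns (features, last_conv, pool_argmax)."""
        data = v.data if isinstance(v, VolumeGrid) else np.asarray(v)
        if self.config.input_shape is not None and tuple(data.shape) != tuple(
            self.config.input_shape
        ):
            raise ValueError(
                f"volume shape {data.shape} does not match configured "
                f"input_shape {self.config.input_shape}"
            )
        x = self._normalize(data)[None]  # (1, X, Y, Z)
        conv = self._backbone(x)
        pooled, arg = head_pool(conv, self.config.pool_kernel, self.config.pool_stride,
                                self.config.pool_padding)
        return pooled.reshape(-1), conv, arg

    def extract(self, v: VolumeGrid | np.ndarray) -> np.ndarray:
        """Flattened feature vector; pure (bit-identical on repeated calls)."""
        return self.forward(v)[0]

    def pooled_shape(self, input_shape: tuple[int, int, int]):
        return pooled_shape(self.config, input_shape)

    def output_dim(self, input_shape: tuple[int, int, int]) -> int:
        return output_dim(self.config, input_shape)

    def feature_names(self, input_shape: tuple[int, int, int]) -> list[str]:
        n = self.output_dim(input_shape)
        return [f"{self.config.name_prefix}_{i}" for i in range(n)]


def build_extractor(config: ExtractorConfig) -> DeepExtractor:
    return DeepExtractor(config)
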