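"""Residual U-Net deblurrer (D-CNN).

A 5-level encoder-decoder with 23 convolution layers in total and feature
widths running from ``channel_min`` to ``channel_max = 16 * channel_min``
(32 to 512 at full size).  The tally behind "23":

    5 encoder levels x 2 convs (3x3)      = 10
    4 decoder levels x 2 convs (3x3)      =  8
    4 transposed convs (2x2, stride 2)    =  4
    1 final 1x1 conv to one channel       =  1
                                           ----
                                            23

Each 3x3 conv is followed by ReLU then batch normalization; levels are
joined by 2x2 max pooling (down) and 2x2 transposed convolution plus skip
concatenation (up).  The single-channel head passes through tanh, is added
to the sensor input as a residual, and the sum is clamped to [0, 1].  With
four poolings, input sides must be multiples of 16.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import grad
from .grad import Param
from .image_formation import SensorImage

__all__ = ["NetworkSpec", "UNet", "build_network", "deblur",
           "save_checkpoint", "load_checkpoint"]

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture contract for the deblurring U-Net."""

    n_conv_layers: int = 23
    channel_min: int = 32
    channel_max: int = 512
    depth_levels: int = 5
    input_multiple: int = 16

    def __post_init__(self):
        if self.n_conv_layers != 5 * self.depth_levels - 2:
            raise ValueError(
                f"a {self.depth_levels}-level U-Net of this topology has "
                f"{5 * self.depth_levels - 2} conv layers, not {self.n_conv_layers}")
        if self.channel_max != self.channel_min * 2 ** (self.depth_levels - 1):
            raise ValueError("channel_max must be channel_min * 2^(levels-1)")
        if self.input_multiple != 2 ** (self.depth_levels - 1):
            raise ValueError("input_multiple must be 2^(levels-1)")

    @classmethod
    def desk_scale(cls, channel_min: int = 8) -> "NetworkSpec":
        """Same 23-layer topology at reduced width, for CPU-scale training."""
        return cls(channel_min=channel_min, channel_max=channel_min * 16)


def _conv_block(cin: int, cout: int, rng, dtype):
    return grad.Sequential(
        grad.Conv2d(cin, cout, 3, rng, dtype), grad.ReLU(), grad.BatchNorm2d(cout, dtype=dtype),
        grad.Conv2d(cout, cout, 3, rng, dtype), grad.ReLU(), grad.BatchNorm2d(cout, dtype=dtype),
    )


class UNet:
    """The D-CNN: encoder-decoder with residual tanh head and clamp."""

    def __init__(self, spec: NetworkSpec, seed: int = 0, dtype=np.float64):
        self.spec = spec
        self.seed = seed
        self.dtype = dtype
        self.training_stage = "stage1"
        rng = np.random.default_rng(seed)
        ch = [spec.channel_min * 2 ** i for i in range(spec.depth_levels)]
        self.channels = ch
        self.enc = [_conv_block(1 if i == 0 else ch[i - 1], ch[i], rng, dtype)
                    for i in range(spec.depth_levels)]
        self.pools = [grad.MaxPool2d() for _ in range(spec.depth_levels - 1)]
        self.ups = [grad.ConvTranspose2d(ch[i + 1], ch[i], rng, dtype)
                    for i in reversed(range(spec.depth_levels - 1))]
        self.dec = [_conv_block(2 * ch[i], ch[i], rng, dtype)
                    for i in reversed(range(spec.depth_levels - 1))]
        self.head = grad.Conv2d(ch[0], 1, 1, rng, dtype)
        self.tanh = grad.Tanh()
        self._modules = self.enc + self.pools + self.ups + self.dec + [self.head]
        self._cache = None

    # -- bookkeeping ------------------------------------------------------

    def params(self) -> list[Param]:
        return [p for m in self._modules for p in m.params()]

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    def conv_layer_count(self) -> int:
        """Count convolution layers the way the architecture tally does."""
        n = 0
        for m in self._modules:
            stack = m.layers if isinstance(m, grad.Sequential) else [m]
            n += sum(isinstance(x, (grad.Conv2d, grad.ConvTranspose2d)) for x in stack)
        return n

    def train(self):
        for m in self._modules:
            m.train()

    def eval(self):
        for m in self._modules:
            m.eval()

    # -- forward / backward ------------------------------------------------

    def _check_shape(self, x: np.ndarray) -> None:
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError(f"expected (N, 1, H, W), got {x.shape}")
        mult = self.spec.input_multiple
        if x.shape[2] % mult or x.shape[3] % mult:
            raise ValueError(f"input sides must be multiples of {mult}, "
                             f"got {x.shape[2]}x{x.shape[3]}")

    def forward(self, x: np.ndarray) -> np.ndarray:
        """clamp(x + tanh(residual), 0, 1); shape-preserving."""
        self._check_shape(x)
        x = np.ascontiguousarray(x, dtype=self.dtype)
        skips = []
        t = x
        for i, block in enumerate(self.enc):
            t = block.forward(t)
            if i < len(self.pools):
                skips.append(t)
                t = self.pools[i].forward(t)
        for up, dec, skip in zip(self.ups, self.dec, reversed(skips)):
            t = up.forward(t)
            t = dec.forward(np.concatenate([skip, t], axis=1))
        residual = self.tanh.forward(self.head.forward(t))
        pre = x + residual
        out = np.clip(pre, 0.0, 1.0)
        self._cache = (pre > 0) & (pre < 1)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        """Propagate to the input; returns dL/dx (for joint optics training)."""
        if self._cache is None:
            raise RuntimeError("backward before forward")
        dpre = dout * self._cache
        self._cache = None
        dt = self.head.backward(self.tanh.backward(dpre))
        nlev = len(self.enc)
        # decoder blocks unwind shallowest-first; dec[j] consumed skips[nlev-2-j]
        dskips = [None] * (nlev - 1)
        for j in reversed(range(nlev - 1)):
            dcat = self.dec[j].backward(dt)
            nskip = dcat.shape[1] // 2
            dskips[nlev - 2 - j] = dcat[:, :nskip]
            dt = self.ups[j].backward(dcat[:, nskip:])
        dt = self.enc[nlev - 1].backward(dt)  # bottleneck
        for i in reversed(range(nlev - 1)):
            dt = self.pools[i].backward(dt)
            dt = dt + dskips[i]
            dt = self.enc[i].backward(dt)
        return dpre + dt  # residual shortcut + network path

    # -- serialization -----------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        arrays = {}
        for i, p in enumerate(self.params()):
            arrays[f"param_{i:03d}"] = p.value
        bn_idx = 0
        for m in self._modules:
            stack = m.layers if isinstance(m, grad.Sequential) else [m]
            for layer in stack:
                if isinstance(layer, grad.BatchNorm2d):
                    arrays[f"bn_{bn_idx:03d}_mean"] = layer.running_mean
                    arrays[f"bn_{bn_idx:03d}_var"] = layer.running_var
                    bn_idx += 1
        return arrays

    def load_state(self, arrays: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            value = arrays[f"param_{i:03d}"]
            if value.shape != p.value.shape:
                raise ValueError(f"checkpoint shape mismatch at param {i}")
            p.value = value.astype(self.dtype)
        bn_idx = 0
        for m in self._modules:
            stack = m.layers if isinstance(m, grad.Sequential) else [m]
            for layer in stack:
                if isinstance(layer, grad.BatchNorm2d):
                    layer.running_mean = arrays[f"bn_{bn_idx:03d}_mean"].astype(self.dtype)
                    layer.running_var = arrays[f"bn_{bn_idx:03d}_var"].astype(self.dtype)
                    bn_idx += 1


def build_network(spec: NetworkSpec, seed: int = 0, dtype=np.float64) -> UNet:
    """Deterministically initialized U-Net (uniform fan-in scheme per seed)."""
    return UNet(spec, seed=seed, dtype=dtype)


def deblur(net: UNet, sensor) -> np.ndarray:
    """Evaluate the D-CNN on one sensor image (2-D array or SensorImage)."""
    img = sensor.image if isinstance(sensor, SensorImage) else np.asarray(sensor)
    net.eval()
    out = net.forward(img[None, None].astype(net.dtype))
    return out[0, 0]


def save_checkpoint(net: UNet, path) -> None:
    meta = {"version": CHECKPOINT_VERSION, "spec": asdict(net.spec),
            "seed": net.seed, "stage": net.training_stage}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **net.state_arrays())


def load_checkpoint(path, dtype=np.float64) -> UNet:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta["version"] > CHECKPOINT_VERSION:
            raise ValueError(f"checkpoint version {meta['version']} is newer "
                             "than this package supports")
        net = UNet(NetworkSpec(**meta["spec"]), seed=meta["seed"], dtype=dtype)
        net.training_stage = meta["stage"]
        net.load_state({k: data[k] for k in data.files if k != "__meta__"})
    return net
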