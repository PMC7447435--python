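"""U-Net / Residual U-Net for boundary prediction, built on the numpy layers.

The network follows the encoder–decoder scheme with skip connections:
each level applies a double convolution block (normalisation → convolution
→ ReLU, twice), levels are linked by 2× max-pooling on the way down and
nearest-neighbour upsampling + channel concatenation on the way up, and a
final 1×1 convolution produces a single-channel logit map.  All
convolutions are "same", so the output shape equals the input shape —
provided every spatial extent is divisible by ``2^(depth-1)``.

The residual variant adds an identity (or 1×1-projected) shortcut around
every double-conv block, which adds parameters relative to the plain net
of equal width.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .layers import BatchNorm, Conv, GroupNorm, Layer, MaxPool, Param, ReLU, Upsample, sigmoid

__all__ = ["NetworkConfig", "UNet", "build_network", "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyper-parameters of the boundary-prediction network.

    ``feature_maps`` lists the channel width per level (strictly
    increasing, ≥ 2 levels); ``normalization`` is ``"group"`` (default,
    suited to single-patch iterations) or ``"batch"`` (multi-patch);
    ``dims`` selects 3D volumes or 2D slices.  The final activation is a
    sigmoid, applied in :meth:`UNet.predict`.
    """

    architecture: str = "unet"
    dims: int = 3
    in_channels: int = 1
    out_channels: int = 1
    feature_maps: tuple[int, ...] = (16, 32)
    normalization: str = "group"
    group_count: int = 8
    kernel_size: int = 3

    def __post_init__(self) -> None:
        if self.architecture not in ("unet", "residual_unet"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.dims not in (2, 3):
            raise ValueError("dims must be 2 or 3")
        fmaps = tuple(int(f) for f in self.feature_maps)
        object.__setattr__(self, "feature_maps", fmaps)
        if len(fmaps) < 2:
            raise ValueError("at least 2 levels (feature map entries) required")
        if any(b <= a for a, b in zip(fmaps, fmaps[1:])):
            raise ValueError("feature maps must be strictly increasing with depth")
        if self.normalization not in ("batch", "group"):
            raise ValueError("normalization must be 'batch' or 'group'")
        if self.group_count < 1:
            raise ValueError("group_count must be >= 1")

    @property
    def depth(self) -> int:
        return len(self.feature_maps)

    @property
    def divisor(self) -> int:
        return 2 ** (self.depth - 1)


class _Block:
    """Double conv block: (norm → conv → ReLU) × 2, optionally residual."""

    def __init__(self, cfg: NetworkConfig, cin: int, cout: int, rng: np.random.Generator):
        def norm(c):
            if cfg.normalization == "batch":
                return BatchNorm(c)
            return GroupNorm(c, cfg.group_count)

        self.layers: list[Layer] = [
            norm(cin),
            Conv(cin, cout, cfg.kernel_size, cfg.dims, rng),
            ReLU(),
            norm(cout),
            Conv(cout, cout, cfg.kernel_size, cfg.dims, rng),
            ReLU(),
        ]
        self.residual = cfg.architecture == "residual_unet"
        self.proj: Conv | None = None
        if self.residual and cin != cout:
            self.proj = Conv(cin, cout, 1, cfg.dims, rng)

    @property
    def params(self) -> list[Param]:
        out = [p for layer in self.layers for p in layer.params]
        if self.proj is not None:
            out += self.proj.params
        return out

    def forward(self, x, training=False):
        out = x
        for layer in self.layers[:-1]:
            out = layer.forward(out, training)
        shortcut = None
        if self.residual:
            shortcut = self.proj.forward(x, training) if self.proj is not None else x
            out = out + shortcut
        return self.layers[-1].forward(out, training)  # final ReLU

    def backward(self, grad):
        grad = self.layers[-1].backward(grad)
        g_main = grad
        for layer in reversed(self.layers[:-1]):
            g_main = layer.backward(g_main)
        if self.residual:
            g_short = self.proj.backward(grad) if self.proj is not None else grad
            g_main = g_main + g_short
        return g_main


class UNet:
    """Encoder–decoder boundary-prediction network (numpy implementation)."""

    def __init__(self, config: NetworkConfig, rng_seed: int = 0):
        self.config = config
        rng = np.random.default_rng(rng_seed)
        fmaps = config.feature_maps
        self.encoders: list[_Block] = []
        cin = config.in_channels
        for f in fmaps:
            self.encoders.append(_Block(config, cin, f, rng))
            cin = f
        self.pool = MaxPool()
        self.up = Upsample()
        self.decoders: list[_Block] = []
        for i in range(len(fmaps) - 2, -1, -1):
            self.decoders.append(_Block(config, fmaps[i + 1] + fmaps[i], fmaps[i], rng))
        self.final = Conv(fmaps[0], config.out_channels, 1, config.dims, rng)
        self._pools: list[MaxPool] = []
        self._ups: list[Upsample] = []

    @property
    def params(self) -> list[Param]:
        out = []
        for block in self.encoders + self.decoders:
            out += block.params
        out += self.final.params
        return out

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params))

    def _check_shape(self, x: np.ndarray) -> None:
        spatial = x.shape[2:]
        d = self.config.divisor
        if len(spatial) != self.config.dims:
            raise ValueError(f"expected {self.config.dims} spatial dims, got shape {x.shape}")
        if any(s % d for s in spatial):
            raise ValueError(
                f"spatial shape {spatial} must be divisible by 2^(depth-1) = {d}; "
                "mirror-pad the input (predict_tiled does this automatically)"
            )

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Logit map of shape equal to the input ``(N, 1, *spatial)``."""
        from .layers import DTYPE
        x = np.asarray(x, dtype=DTYPE)
        self._check_shape(x)
        skips = []
        out = x
        self._pools = []
        for i, enc in enumerate(self.encoders):
            out = enc.forward(out, training)
            if i < len(self.encoders) - 1:
                skips.append(out)
                pool = MaxPool()
                out = pool.forward(out, training)
                self._pools.append(pool)
        self._ups = []
        self._skip_channels = []
        for dec, skip in zip(self.decoders, reversed(skips)):
            up = Upsample()
            out = up.forward(out, training)
            self._ups.append(up)
            self._skip_channels.append((out.shape[1], skip.shape[1]))
            out = np.concatenate([out, skip], axis=1)
            out = dec.forward(out, training)
        return self.final.forward(out, training)

    def backward(self, grad: np.ndarray) -> None:
        grad = self.final.backward(grad)
        skip_grads = []
        for dec, up, (c_up, c_skip) in zip(
            reversed(self.decoders), reversed(self._ups), reversed(self._skip_channels)
        ):
            grad = dec.backward(grad)
            g_up, g_skip = grad[:, :c_up], grad[:, c_up:]
            skip_grads.append(g_skip)
            grad = up.backward(g_up)
        skip_grads.reverse()  # now bottom-up: skip_grads[i] pairs with encoder i
        for i in range(len(self.encoders) - 1, -1, -1):
            if i < len(self.encoders) - 1:
                grad = self._pools[i].backward(grad)
                grad = grad + skip_grads[len(skip_grads) - 1 - i]
            grad = self.encoders[i].backward(grad)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Boundary probabilities in [0, 1] (sigmoid of the logits)."""
        return sigmoid(self.forward(x, training=False))

    def state(self) -> list[np.ndarray]:
        arrays = [p.value.copy() for p in self.params]
        for block in self.encoders + self.decoders:
            for layer in block.layers:
                if isinstance(layer, BatchNorm):
                    arrays += [layer.running_mean.copy(), layer.running_var.copy()]
        return arrays

    def load_state(self, arrays: list[np.ndarray]) -> None:
        it = iter(arrays)
        for p in self.params:
            p.value[...] = next(it)
        for block in self.encoders + self.decoders:
            for layer in block.layers:
                if isinstance(layer, BatchNorm):
                    layer.running_mean[...] = next(it)
                    layer.running_var[...] = next(it)


def build_network(config: NetworkConfig | None = None, rng_seed: int = 0) -> UNet:
    """Instantiate a (residual) U-Net; parameter values are deterministic
    given the config and seed."""
    return UNet(config or NetworkConfig(), rng_seed=rng_seed)


def save_checkpoint(model: UNet, path) -> None:
    """Persist weights plus the architecture config (npz + embedded JSON)."""
    cfg = model.config
    meta = json.dumps(
        {
            "architecture": cfg.architecture,
            "dims": cfg.dims,
            "in_channels": cfg.in_channels,
            "out_channels": cfg.out_channels,
            "feature_maps": list(cfg.feature_maps),
            "normalization": cfg.normalization,
            "group_count": cfg.group_count,
            "kernel_size": cfg.kernel_size,
        }
    )
    arrays = {f"arr_{i}": a for i, a in enumerate(model.state())}
    np.savez(path, config=np.array(meta), **arrays)


def load_checkpoint(path) -> UNet:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["config"]))
        meta["feature_maps"] = tuple(meta["feature_maps"])
        model = UNet(NetworkConfig(**meta))
        arrays = [data[f"arr_{i}"] for i in range(len(data.files) - 1)]
    model.load_state(arrays)
    return model
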