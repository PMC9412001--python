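"""The 2D U-Net shared across the three slicing orientations.

A single network consumes a two-channel slice (channel 0 = baseline,
channel 1 = follow-up) and emits per-pixel class probabilities via a
two-channel softmax head; the foreground channel is the new-lesion
probability. Encoder levels double the channel width and halve the spatial
size (2×2 max pooling); the decoder mirrors them with 2×2 transpose
convolutions and skip concatenation. All convolutions are 3×3 with "same"
padding, each followed by batch normalization and ReLU.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from ._nn import (Conv2D, BatchNorm2D, ReLU, MaxPool2, ConvTranspose2,
                  softmax_channels)

__all__ = ["UNetConfig", "UNet2D", "SlicePair", "ProbabilitySlice",
           "build_unet", "predict_slice", "save_checkpoint", "load_checkpoint"]

ORIENTATIONS = ("sagittal", "coronal", "axial")


@dataclasses.dataclass(frozen=True)
class UNetConfig:
    in_channels: int = 2
    base_channels: int = 32
    depth: int = 5
    slice_size: int = 256

    def __post_init__(self) -> None:
        if self.in_channels != 2:
            raise ValueError("the network takes exactly 2 input channels "
                             "(baseline + follow-up slice)")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.slice_size % (2 ** (self.depth - 1)) != 0:
            raise ValueError(
                f"slice_size {self.slice_size} not divisible by "
                f"2^(depth-1) = {2 ** (self.depth - 1)}")

    def channels(self, level: int) -> int:
        return self.base_channels * (2 ** level)


@dataclasses.dataclass
class SlicePair:
    """One 2-channel input slice: (2, N, N), channel 0 baseline, 1 follow-up."""
    data: np.ndarray
    orientation: str
    index: int

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3 or self.data.shape[0] != 2:
            raise ValueError(f"slice pair must be (2, N, N), got {self.data.shape}")
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"unknown orientation {self.orientation!r}")


@dataclasses.dataclass
class ProbabilitySlice:
    """Foreground probability map for one slice, values in [0, 1]."""
    data: np.ndarray
    orientation: str
    index: int


def _conv_block(c_in: int, c_out: int, rng: np.random.Generator) -> list:
    return [Conv2D(c_in, c_out, 3, rng), BatchNorm2D(c_out), ReLU(),
            Conv2D(c_out, c_out, 3, rng), BatchNorm2D(c_out), ReLU()]


class UNet2D:
    """U-Net with explicit forward/backward passes (NumPy engine)."""

    def __init__(self, config: UNetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        d = config.depth
        self.enc_blocks = []
        for lvl in range(d):
            c_in = config.in_channels if lvl == 0 else config.channels(lvl - 1)
            self.enc_blocks.append(_conv_block(c_in, config.channels(lvl), rng))
        self.pools = [MaxPool2() for _ in range(d - 1)]
        self.ups = []
        self.dec_blocks = []
        for lvl in range(d - 2, -1, -1):
            self.ups.append(ConvTranspose2(config.channels(lvl + 1),
                                           config.channels(lvl), rng))
            self.dec_blocks.append(
                _conv_block(2 * config.channels(lvl), config.channels(lvl), rng))
        self.head = Conv2D(config.channels(0), 2, 1, rng)

    # ---- plumbing ------------------------------------------------------
    def layers(self) -> list:
        out = []
        for blk in self.enc_blocks:
            out.extend(blk)
        out.extend(self.pools)
        for up, blk in zip(self.ups, self.dec_blocks):
            out.append(up)
            out.extend(blk)
        out.append(self.head)
        return out

    def n_parameters(self) -> int:
        return sum(int(np.prod(p.shape)) for l in self.layers()
                   for p in l.params.values())

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, layer in enumerate(self.layers()):
            for k, v in layer.params.items():
                state[f"layer{i}.{k}"] = v
            if isinstance(layer, BatchNorm2D):
                state[f"layer{i}.running_mean"] = layer.running_mean
                state[f"layer{i}.running_var"] = layer.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers()):
            for k in layer.params:
                layer.params[k][...] = state[f"layer{i}.{k}"]
            if isinstance(layer, BatchNorm2D):
                layer.running_mean[...] = state[f"layer{i}.running_mean"]
                layer.running_var[...] = state[f"layer{i}.running_var"]

    # ---- forward / backward -------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """(B, 2, N, N) → class probabilities (B, 2, N, N)."""
        x = np.asarray(x)
        if x.dtype not in (np.float32, np.float64):
            x = x.astype(np.float32)
        if x.shape[2] != self.config.slice_size or x.shape[3] != self.config.slice_size:
            raise ValueError(
                f"input spatial size {x.shape[2:]} != configured "
                f"{self.config.slice_size}")
        skips = []
        h = x
        for lvl, blk in enumerate(self.enc_blocks):
            for layer in blk:
                h = layer.forward(h, train)
            if lvl < len(self.pools):
                skips.append(h)
                h = self.pools[lvl].forward(h, train)
        for up, blk in zip(self.ups, self.dec_blocks):
            h = up.forward(h, train)
            skip = skips.pop()
            h = np.concatenate([skip, h], axis=1)
            for layer in blk:
                h = layer.forward(h, train)
        z = self.head.forward(h, train)
        self._probs = softmax_channels(z)
        return self._probs

    def backward(self, dprobs: np.ndarray) -> None:
        """Backpropagate a gradient taken w.r.t. the softmax probabilities."""
        p = self._probs
        # softmax Jacobian: dL/dz_c = p_c (dL/dp_c - sum_k dL/dp_k p_k)
        dz = p * (dprobs - (dprobs * p).sum(axis=1, keepdims=True))
        g = self.head.backward(dz)
        d = self.config.depth
        skip_grads: dict[int, np.ndarray] = {}
        # decoder stages were run for lvl = d-2 .. 0; undo them in reverse
        for i in reversed(range(len(self.ups))):
            lvl = d - 2 - i
            for layer in reversed(self.dec_blocks[i]):
                g = layer.backward(g)
            c_skip = self.config.channels(lvl)
            skip_grads[lvl] = np.ascontiguousarray(g[:, :c_skip])
            g = self.ups[i].backward(np.ascontiguousarray(g[:, c_skip:]))
        # encoder, deepest level first; skip taps rejoin before each block
        for lvl in reversed(range(d)):
            if lvl < d - 1:
                g = self.pools[lvl].backward(g) + skip_grads[lvl]
            for layer in reversed(self.enc_blocks[lvl]):
                g = layer.backward(g)


def build_unet(config: UNetConfig, seed: int = 0) -> UNet2D:
    return UNet2D(config, seed=seed)


def predict_slice(model: UNet2D, slice_pair: SlicePair) -> ProbabilitySlice:
    """Run one slice through the network in evaluation mode."""
    probs = model.forward(slice_pair.data[None], train=False)
    return ProbabilitySlice(data=probs[0, 1], orientation=slice_pair.orientation,
                            index=slice_pair.index)


def save_checkpoint(model: UNet2D, path: str | Path) -> None:
    state = model.state_dict()
    cfg = json.dumps(dataclasses.asdict(model.config))
    np.savez(str(path), __config__=np.frombuffer(cfg.encode(), dtype=np.uint8),
             **state)


def load_checkpoint(path: str | Path) -> UNet2D:
    with np.load(str(path)) as npz:
        cfg = json.loads(bytes(npz["__config__"]).decode())
        state = {k: npz[k] for k in npz.files if k != "__config__"}
    model = UNet2D(UNetConfig(**cfg))
    model.load_state_dict(state)
    return model
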