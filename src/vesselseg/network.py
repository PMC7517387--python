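"""MSFFU-Net and classic U-Net builders.

The MSFFU-Net is an encoder–decoder segmentation network.  The encoder
repeats (two multi-scale inception blocks, then a 2×2/stride-2 max-pool)
``depth`` times, doubling the channel count at every downsampling step; the
max-pool records its argmax indices.  Each multi-scale block runs three
parallel branches — a 1×1 convolution, a 1×1 reduction followed by a 3×3
convolution, and a 1×1 reduction followed by two stacked 3×3 convolutions
(an effective 5×5 receptive field at lower cost) — contributing one quarter,
one half and one quarter of the block's output channels respectively, and
concatenates them.  Every convolution is followed by batch normalization and
a leaky ReLU.

Each decoder stage merges three streams: a 2×2 transpose-convolution
upsampling of the deeper features (halving channels), the index-unpooled
pooled encoder map of the matching stage (the recorded maxima placed back at
their argmax positions, zeros elsewhere), and the encoder skip feature map —
concatenated channel-wise and fused by two 3×3 conv+BN+leaky-ReLU layers.  A
1×1 convolution plus sigmoid head emits a per-pixel vessel probability.

The classic U-Net baseline uses plain double 3×3 conv blocks with ReLU, a
single concatenation skip, and no index unpooling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import _nn
from ._nn import (
    Add, BatchNorm2D, Concat, Conv2D, ConvTranspose2x2, LeakyReLU,
    MaxPool2x2, MaxUnpool2x2, Param, Sigmoid, Tape,
    max_pool_with_indices, unpool_with_indices,
)

__all__ = [
    "NetworkSpec",
    "SegmentationModel",
    "build_msffu_net",
    "build_unet",
    "predict",
    "max_pool_with_indices",
    "unpool_with_indices",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture description.

    depth           number of pooling stages (4 in the full-scale network).
    base_channels   encoder stage-1 output channels; must be divisible by 4
                    so the inception branches can split ¼ : ½ : ¼.
    block           "msffu" (multi-scale inception encoder, dual skips) or
                    "unet" (plain double-conv baseline).
    merge_mode      how the index-unpooled stream joins the decoder merge:
                    "concat" (default) or "sum" into the upsampled stream.
    """

    depth: int = 4
    base_channels: int = 16
    block: str = "msffu"
    activation: str = "leaky_relu"
    leaky_slope: float = 0.01
    use_batchnorm: bool = True
    out_channels: int = 1
    merge_mode: str = "concat"
    in_channels: int = 1

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.base_channels < 4 or self.base_channels % 4:
            raise ValueError("base_channels must be >= 4 and divisible by 4")
        if self.out_channels < 1:
            raise ValueError("out_channels must be >= 1")
        if self.block not in ("msffu", "unet"):
            raise ValueError("block must be 'msffu' or 'unet'")
        if self.merge_mode not in ("concat", "sum"):
            raise ValueError("merge_mode must be 'concat' or 'sum'")
        if self.activation not in ("leaky_relu", "relu"):
            raise ValueError("activation must be 'leaky_relu' or 'relu'")


def _act(spec: NetworkSpec) -> LeakyReLU:
    # ReLU is leaky ReLU with slope 0
    return LeakyReLU(spec.leaky_slope if spec.activation == "leaky_relu" else 0.0)


class _ConvBNAct:
    """conv -> (BN) -> activation, as a reusable unit."""

    def __init__(self, in_ch: int, out_ch: int, k: int, spec: NetworkSpec,
                 rng: np.random.Generator):
        self.conv = Conv2D(in_ch, out_ch, k, rng, bias=not spec.use_batchnorm)
        self.bn = BatchNorm2D(out_ch) if spec.use_batchnorm else None
        self.act = _act(spec)

    def __call__(self, tape: Tape, x: np.ndarray) -> np.ndarray:
        x = tape.apply(self.conv, x)
        if self.bn is not None:
            x = tape.apply(self.bn, x)
        return tape.apply(self.act, x)

    def layers(self) -> list[_nn.Layer]:
        return [self.conv] + ([self.bn] if self.bn else []) + [self.act]


class MultiScaleBlock:
    """Three-branch inception block with a ¼ : ½ : ¼ channel split.

    Branch widths for ``out_channels = c``: 1×1 → c/4; 1×1 reduce then
    3×3 → c/2; 1×1 reduce then two 3×3 → c/4.  The 1×1 reductions compress to
    half the branch's output width.  Spatial size is preserved (stride 1,
    same padding); downsampling lives in the dedicated pooling op.
    """

    def __init__(self, in_ch: int, out_ch: int, spec: NetworkSpec,
                 rng: np.random.Generator):
        if out_ch % 4:
            raise ValueError(f"multiscale block out_channels must be divisible by 4, got {out_ch}")
        q, h = out_ch // 4, out_ch // 2
        self.a1 = _ConvBNAct(in_ch, q, 1, spec, rng)
        self.b_reduce = _ConvBNAct(in_ch, max(h // 2, 1), 1, spec, rng)
        self.b3 = _ConvBNAct(max(h // 2, 1), h, 3, spec, rng)
        self.c_reduce = _ConvBNAct(in_ch, max(q // 2, 1), 1, spec, rng)
        self.c3a = _ConvBNAct(max(q // 2, 1), q, 3, spec, rng)
        self.c3b = _ConvBNAct(q, q, 3, spec, rng)
        self.cat = Concat()
        self.out_channels = out_ch

    def __call__(self, tape: Tape, x: np.ndarray) -> np.ndarray:
        a = self.a1(tape, x)
        b = self.b3(tape, self.b_reduce(tape, x))
        c = self.c3b(tape, self.c3a(tape, self.c_reduce(tape, x)))
        return tape.apply(self.cat, a, b, c)

    def layers(self) -> list[_nn.Layer]:
        units = [self.a1, self.b_reduce, self.b3, self.c_reduce, self.c3a, self.c3b]
        return [l for u in units for l in u.layers()] + [self.cat]


class DoubleConvBlock:
    """Two 3×3 conv+act (plus BN when enabled) — the classic U-Net block."""

    def __init__(self, in_ch: int, out_ch: int, spec: NetworkSpec,
                 rng: np.random.Generator):
        self.c1 = _ConvBNAct(in_ch, out_ch, 3, spec, rng)
        self.c2 = _ConvBNAct(out_ch, out_ch, 3, spec, rng)
        self.out_channels = out_ch

    def __call__(self, tape: Tape, x: np.ndarray) -> np.ndarray:
        return self.c2(tape, self.c1(tape, x))

    def layers(self) -> list[_nn.Layer]:
        return self.c1.layers() + self.c2.layers()


class SegmentationModel:
    """Encoder–decoder pixel classifier built from a :class:`NetworkSpec`."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.seed = seed
        b = spec.base_channels
        msffu = spec.block == "msffu"
        Block = MultiScaleBlock if msffu else DoubleConvBlock

        self.enc_blocks: list[tuple] = []
        self.pools: list[MaxPool2x2] = []
        in_ch = spec.in_channels
        for i in range(spec.depth):
            ch = b * 2**i
            blk1, blk2 = Block(in_ch, ch, spec, rng), Block(ch, ch, spec, rng)
            self.enc_blocks.append((blk1, blk2))
            self.pools.append(MaxPool2x2())
            in_ch = ch
        bott = b * 2**spec.depth
        self.bottleneck = (Block(in_ch, bott, spec, rng), Block(bott, bott, spec, rng))

        self.dec_stages = []
        in_ch = bott
        for i in reversed(range(spec.depth)):
            skip_ch = b * 2**i
            up = ConvTranspose2x2(in_ch, skip_ch, rng)
            unpool = MaxUnpool2x2(self.pools[i]) if msffu else None
            if msffu:
                fuse_in = 3 * skip_ch if spec.merge_mode == "concat" else 2 * skip_ch
            else:
                fuse_in = 2 * skip_ch
            fuse1 = _ConvBNAct(fuse_in, skip_ch, 3, spec, rng)
            fuse2 = _ConvBNAct(skip_ch, skip_ch, 3, spec, rng)
            merge = Concat()
            adder = Add() if (msffu and spec.merge_mode == "sum") else None
            self.dec_stages.append((up, unpool, merge, adder, fuse1, fuse2))
            in_ch = skip_ch

        self.head = Conv2D(in_ch, spec.out_channels, 1, rng)
        self.head_sigmoid = Sigmoid()
        self._tape: Tape | None = None
        self._output: np.ndarray | None = None
        self._input: np.ndarray | None = None

    # ------------------------------------------------------------------ utils
    def _all_layers(self) -> list[_nn.Layer]:
        out: list[_nn.Layer] = []
        for blk1, blk2 in self.enc_blocks:
            out += blk1.layers() + blk2.layers()
        out += self.pools
        out += self.bottleneck[0].layers() + self.bottleneck[1].layers()
        for up, unpool, merge, adder, fuse1, fuse2 in self.dec_stages:
            out.append(up)
            if unpool is not None:
                out.append(unpool)
            out.append(merge)
            if adder is not None:
                out.append(adder)
            out += fuse1.layers() + fuse2.layers()
        out += [self.head, self.head_sigmoid]
        return out

    def parameters(self) -> list[Param]:
        return [p for layer in self._all_layers() for p in layer.params()]

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.parameters())

    def weight_norm_sq(self) -> float:
        return float(sum((p.value.astype(np.float64) ** 2).sum() for p in self.parameters()))

    def set_training(self, training: bool) -> None:
        for layer in self._all_layers():
            layer.training = training

    # ---------------------------------------------------------------- forward
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Map N×C×H×W input to N×out_channels×H×W probabilities in [0, 1]."""
        x = np.asarray(x, dtype=_nn.DTYPE)
        if x.ndim != 4 or x.shape[1] != self.spec.in_channels:
            raise ValueError(
                f"expected N×{self.spec.in_channels}×H×W input, got {x.shape}")
        H, W = x.shape[2], x.shape[3]
        div = 2**self.spec.depth
        if H % div or W % div:
            raise ValueError(
                f"input {H}×{W} not divisible by 2^depth = {div}; pad the input "
                f"(predict() does this automatically)")
        self.set_training(training)
        tape = Tape()
        skips: list[np.ndarray] = []
        pooled_maps: list[np.ndarray] = []
        for (blk1, blk2), pool in zip(self.enc_blocks, self.pools):
            x = blk2(tape, blk1(tape, x))
            skips.append(x)
            x = tape.apply(pool, x)
            pooled_maps.append(x)
        x = self.bottleneck[1](tape, self.bottleneck[0](tape, x))
        for stage_idx, (up, unpool, merge, adder, fuse1, fuse2) in enumerate(self.dec_stages):
            i = self.spec.depth - 1 - stage_idx
            u = tape.apply(up, x)
            streams = [u]
            if unpool is not None:
                sparse = tape.apply(unpool, pooled_maps[i])
                if adder is not None:
                    u = tape.apply(adder, u, sparse)
                    streams = [u]
                else:
                    streams.append(sparse)
            streams.append(skips[i])
            x = tape.apply(merge, *streams)
            x = fuse2(tape, fuse1(tape, x))
        logits = tape.apply(self.head, x)
        out = tape.apply(self.head_sigmoid, logits)
        self._tape, self._output = tape, out
        return out

    def backward(self, grad_out: np.ndarray) -> None:
        """Backpropagate d(loss)/d(output) into parameter ``.grad`` buffers."""
        if self._tape is None:
            raise RuntimeError("forward() must be called before backward()")
        self._tape.backward(self._output, np.asarray(grad_out, dtype=_nn.DTYPE))

    def summary(self) -> str:
        lines = [f"{self.spec.block} network: depth={self.spec.depth}, "
                 f"base_channels={self.spec.base_channels}, "
                 f"parameters={self.n_parameters():,}"]
        enc = [f"  encoder stage {i + 1}: {self.spec.base_channels * 2**i} ch"
               for i in range(self.spec.depth)]
        lines += enc
        lines.append(f"  bottleneck: {self.spec.base_channels * 2**self.spec.depth} ch")
        lines.append(f"  head: {self.spec.out_channels} ch + sigmoid")
        return "\n".join(lines)


def build_msffu_net(spec: NetworkSpec | None = None, seed: int = 0) -> SegmentationModel:
    """MSFFU-Net: inception encoder, index-unpooling decoder, dual skips."""
    spec = spec or NetworkSpec()
    if spec.block != "msffu":
        spec = NetworkSpec(**{**asdict(spec), "block": "msffu"})
    return SegmentationModel(spec, seed=seed)


def build_unet(spec: NetworkSpec | None = None, seed: int = 0) -> SegmentationModel:
    """Classic U-Net baseline: double-conv blocks, ReLU, concatenation skip."""
    spec = spec or NetworkSpec(block="unet", activation="relu")
    if spec.block != "unet":
        spec = NetworkSpec(**{**asdict(spec), "block": "unet", "activation": "relu"})
    return SegmentationModel(spec, seed=seed)


def predict(
    model: SegmentationModel, image: np.ndarray, threshold: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Probability map and thresholded mask for one gray image.

    Accepts uint8 [0, 255] or float [0, 1] H×W input, reflect-pads to the
    next multiple of 2^depth, runs the network in inference mode and crops
    back.  The mask is ``probability >= threshold``.
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D gray image, got shape {img.shape}")
    x = img.astype(np.float64) / (255.0 if img.dtype == np.uint8 else 1.0)
    H, W = x.shape
    div = 2**model.spec.depth
    Hp, Wp = -(-H // div) * div, -(-W // div) * div
    if (Hp, Wp) != (H, W):
        x = np.pad(x, ((0, Hp - H), (0, Wp - W)), mode="reflect")
    prob = model.forward(x[None, None], training=False)[0, 0, :H, :W].astype(np.float64)
    return prob, (prob >= threshold).astype(np.uint8)


def save_checkpoint(model: SegmentationModel, path: str | Path) -> None:
    """Save weights (.npz) plus a JSON sidecar with the NetworkSpec and seed."""
    path = Path(path)
    arrays = {}
    for i, p in enumerate(model.parameters()):
        arrays[f"p{i}"] = p.value
    bn_idx = 0
    for layer in model._all_layers():
        if isinstance(layer, BatchNorm2D):
            arrays[f"bn{bn_idx}_mean"] = layer.running_mean
            arrays[f"bn{bn_idx}_var"] = layer.running_var
            bn_idx += 1
    np.savez(path, **arrays)
    sidecar = {"spec": asdict(model.spec), "seed": model.seed}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path: str | Path) -> SegmentationModel:
    """Rebuild a model from a checkpoint written by :func:`save_checkpoint`."""
    path = Path(path)
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    model = SegmentationModel(NetworkSpec(**sidecar["spec"]), seed=sidecar["seed"])
    data = np.load(path if path.suffix == ".npz" else str(path) + ".npz")
    for i, p in enumerate(model.parameters()):
        p.value[...] = data[f"p{i}"]
    bn_idx = 0
    for layer in model._all_layers():
        if isinstance(layer, BatchNorm2D):
            layer.running_mean[...] = data[f"bn{bn_idx}_mean"]
            layer.running_var[...] = data[f"bn{bn_idx}_var"]
            bn_idx += 1
    return model
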