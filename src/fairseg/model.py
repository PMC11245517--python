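"""Hybrid encoder-decoder segmentation network.

A U-Net-style decoder on top of a four-layer residual encoder.  Each encoder
layer is two residual basic blocks whose first block downsamples (3x3
kernels, stride 2, padding 1), doubling the feature width along
``encoder_widths`` (default 64 -> 128 -> 256 -> 512).  The decoder mirrors the
encoder: each of its first four blocks fuses, by channel-wise concatenation,
the first-block encoder feature map of matching resolution with the upsampled
output of the previous decoder block, followed by two conv-BN-ReLU stages;
remaining upsampling stages (and the 1x1 class head) restore the input
resolution.  A ``width_multiplier`` scales all widths for desk-scale use.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn

__all__ = [
    "ModelConfig",
    "SegNet",
    "build_model",
    "predict_masks",
    "masks_from_probabilities",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class ModelConfig:
    in_channels: int = 1
    n_classes: int = 4                      # knee: 4, hip: 3
    encoder_widths: tuple[int, int, int, int] = (64, 128, 256, 512)
    width_multiplier: float = 1.0
    use_stem: bool = True
    kernel: int = 3                          # fixed encoder geometry
    stride: int = 2
    padding: int = 1
    # head bias init for the background class (log-prior-style init: most
    # pixels are background, so early training starts from a sensible prior)
    background_bias: float = 2.0

    def __post_init__(self) -> None:
        if len(self.encoder_widths) != 4:
            raise ValueError("exactly 4 encoder layers are required")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.width_multiplier <= 0:
            raise ValueError("width_multiplier must be > 0")
        w = self.scaled_widths()
        if not all(a < b for a, b in zip(w, w[1:])):
            raise ValueError(f"scaled encoder widths must be strictly increasing, got {w}")
        if (self.kernel, self.stride, self.padding) != (3, 2, 1):
            raise ValueError("encoder geometry is fixed at kernel 3, stride 2, padding 1")

    def scaled_widths(self) -> tuple[int, ...]:
        return tuple(max(1, int(round(w * self.width_multiplier)))
                     for w in self.encoder_widths)

    @property
    def downsample_factor(self) -> int:
        return 64 if self.use_stem else 16

    def to_dict(self) -> dict:
        d = asdict(self)
        d["encoder_widths"] = list(self.encoder_widths)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if "encoder_widths" in d:
            d["encoder_widths"] = tuple(d["encoder_widths"])
        return cls(**d)


def _fuse_block(cin, cout, rng, dtype):
    return nn.Sequential(
        nn.Conv2d(cin, cout, 3, 1, 1, rng=rng, dtype=dtype), nn.BatchNorm2d(cout, dtype=dtype), nn.ReLU(),
        nn.Conv2d(cout, cout, 3, 1, 1, rng=rng, dtype=dtype), nn.BatchNorm2d(cout, dtype=dtype), nn.ReLU(),
    )


class SegNet:
    """The assembled network; build with :func:`build_model`."""

    def __init__(self, config: ModelConfig, init_seed: int = 0, dtype=np.float32):
        self.config = config
        self.dtype = dtype
        rng = np.random.default_rng(init_seed)
        w = config.scaled_widths()
        cin = config.in_channels

        if config.use_stem:
            self.stem = nn.Sequential(
                nn.Conv2d(cin, w[0], 7, 2, 3, rng=rng, dtype=dtype),
                nn.BatchNorm2d(w[0], dtype=dtype), nn.ReLU(),
                nn.MaxPool2d(3, 2, 1),
            )
            cin = w[0]
        else:
            self.stem = None

        self.enc_first = []   # downsampling first block of each layer (skip source)
        self.enc_second = []
        c = cin
        for wi in w:
            self.enc_first.append(nn.BasicBlock(c, wi, stride=2, rng=rng, dtype=dtype))
            self.enc_second.append(nn.BasicBlock(wi, wi, stride=1, rng=rng, dtype=dtype))
            c = wi

        # decoder: 4 skip-fusing blocks, deepest first
        self.dec_fuse = [
            _fuse_block(2 * w[3], w[3], rng, dtype),
            _fuse_block(2 * w[2], w[2], rng, dtype),
            _fuse_block(2 * w[1], w[1], rng, dtype),
            _fuse_block(2 * w[0], w[0], rng, dtype),
        ]
        self.dec_up = [  # upsampling into decoder blocks 2..4
            nn.ConvTranspose2d(w[3], w[2], rng=rng, dtype=dtype),
            nn.ConvTranspose2d(w[2], w[1], rng=rng, dtype=dtype),
            nn.ConvTranspose2d(w[1], w[0], rng=rng, dtype=dtype),
        ]
        # remaining stages back to full resolution (1 without stem, 3 with)
        n_final = 1 if not config.use_stem else 3
        self.final_up = []
        for _ in range(n_final):
            self.final_up.append((
                nn.ConvTranspose2d(w[0], w[0], rng=rng, dtype=dtype),
                nn.Sequential(nn.Conv2d(w[0], w[0], 3, 1, 1, rng=rng, dtype=dtype),
                              nn.BatchNorm2d(w[0], dtype=dtype), nn.ReLU()),
            ))
        self.head = nn.Conv2d(w[0], config.n_classes, 1, 1, 0, bias=True,
                              rng=rng, dtype=dtype)
        self.head.bias.value[0] = config.background_bias

    # -- plumbing ----------------------------------------------------------
    def _modules(self):
        mods = [self.stem] if self.stem is not None else []
        mods += self.enc_first + self.enc_second + self.dec_fuse + self.dec_up
        for up, conv in self.final_up:
            mods += [up, conv]
        mods.append(self.head)
        return mods

    def parameters(self) -> list[nn.Param]:
        return nn.collect_params(*self._modules())

    def buffers(self) -> list[np.ndarray]:
        return nn.collect_buffers(*self._modules())

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.ndim != 4:
            raise ValueError("expected a (batch, channels, H, W) array")
        H, W = x.shape[2], x.shape[3]
        f = self.config.downsample_factor
        if H % f or W % f or H < f or W < f:
            raise ValueError(
                f"input spatial size {H}x{W} must be a multiple of the total "
                f"downsampling factor {f} (minimum valid size {f}x{f})"
            )
        x = x.astype(self.dtype, copy=False)
        h = self.stem.forward(x, train) if self.stem is not None else x
        skips = []
        for first, second in zip(self.enc_first, self.enc_second):
            s = first.forward(h, train)
            skips.append(s)
            h = second.forward(s, train)

        d = h
        for i, fuse in enumerate(self.dec_fuse):
            skip = skips[3 - i]
            if i > 0:
                d = self.dec_up[i - 1].forward(d, train)
            assert skip.shape[2:] == d.shape[2:], "skip/decoder resolution mismatch"
            d = fuse.forward(np.concatenate([skip, d], axis=1), train)
        for up, conv in self.final_up:
            d = conv.forward(up.forward(d, train), train)
        logits = self.head.forward(d, train)
        return logits

    def backward(self, dlogits: np.ndarray) -> None:
        g = self.head.backward(dlogits)
        for up, conv in reversed(self.final_up):
            g = up.backward(conv.backward(g))
        w = self.config.scaled_widths()
        skip_grads = []
        for i in range(3, -1, -1):  # decoder blocks in reverse (shallowest first)
            g = self.dec_fuse[i].backward(g)
            wc = w[3 - i]
            skip_grads.append(g[:, :wc])
            g = g[:, wc:]
            if i > 0:
                g = self.dec_up[i - 1].backward(g)
        skip_grads.reverse()  # now indexed like dec_fuse: [s4, s3, s2, s1] grads
        # encoder backward, deepest layer first
        for li in range(3, -1, -1):
            g = self.enc_second[li].backward(g)
            g = g + skip_grads[3 - li]
            g = self.enc_first[li].backward(g)
        if self.stem is not None:
            self.stem.backward(g)

    __call__ = forward


def build_model(config: ModelConfig, init_seed: int = 0, dtype=np.float32) -> SegNet:
    """Construct the network with deterministic initialization."""
    return SegNet(config, init_seed=init_seed, dtype=dtype)


def masks_from_probabilities(fg_probs: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Label maps from per-foreground-class probabilities (classes 1..K).

    A pixel is assigned the foreground class of highest probability provided
    that probability is >= threshold (ties at the maximum go to the lowest
    class index); pixels with no class reaching the threshold are background.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    best = fg_probs.argmax(axis=1)  # first occurrence wins ties -> lowest index
    pmax = np.take_along_axis(fg_probs, best[:, None], axis=1)[:, 0]
    return np.where(pmax >= threshold, best + 1, 0).astype(np.uint8)


def predict_masks(model: SegNet, batch: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Segment a batch: per-class sigmoid probabilities thresholded at 0.5.

    Probabilities are computed per class from the raw class scores (sigmoid
    semantics); assignment follows :func:`masks_from_probabilities`.
    """
    logits = model.forward(batch, train=False)
    fg_probs = nn.sigmoid(logits[:, 1:])
    return masks_from_probabilities(fg_probs, threshold)


def save_checkpoint(model: SegNet, path: str | Path) -> None:
    """Single-file checkpoint embedding the model configuration."""
    arrays = {f"p{i:04d}": p.value for i, p in enumerate(model.parameters())}
    arrays.update({f"b{i:04d}": b for i, b in enumerate(model.buffers())})
    np.savez(path, __config__=np.frombuffer(
        json.dumps(model.config.to_dict()).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> SegNet:
    with np.load(path) as data:
        config = ModelConfig.from_dict(
            json.loads(bytes(data["__config__"]).decode()))
        model = SegNet(config)
        params = model.parameters()
        for i, p in enumerate(params):
            p.value = data[f"p{i:04d}"].copy()
        n_buf = len(model.buffers())
        arrays = [data[f"b{i:04d}"].copy() for i in range(n_buf)]
    _load_model_buffers(model, arrays)
    return model


def _load_model_buffers(model: SegNet, arrays: list[np.ndarray]) -> None:
    i = 0
    for mod in model._modules():
        n = len(mod.buffers())
        mod.load_buffers(arrays[i:i + n])
        i += n
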