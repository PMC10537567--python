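"""Lightweight U-shaped segmentation network.

The encoder opens with a strided *feature-mapping* convolution that halves
the spatial size, followed by a *noise-reduction* block: a depth-wise
convolution and a point-wise convolution that halves the channel count,
bridged by a linear 1x1 projection shortcut.  The body is a sequence of
inverted-residual bottleneck stages (point-wise expand by ``t`` ->
depth-wise 3x3 -> point-wise reduce); the first block of each stage uses
stride 2, the remaining blocks carry identity residuals.  The number of
blocks per stage is non-decreasing with depth so that coarse features
(bruise-sized) and fine features (russet/scald-sized) are both captured.
The decoder repeatedly upsamples bilinearly, optionally concatenates an
encoder skip, and fuses with a 3x3 stride-1 pad-1 convolution.  Every
convolution is followed by batch normalization and ReLU6, except the
1x1 sigmoid head, whose output is upsampled to the input resolution.

Two skip policies are provided: ``noise_block_only`` routes a single
encoder->decoder connection from the noise-reduction block to the
matching-resolution decoder level; ``full_unet`` concatenates every
encoder stage output at its matching decoder level.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from . import nn
from .nn import Tensor


@dataclass
class NetworkConfig:
    """Hyperparameters of the U-shaped network.

    Defaults target the compact regime (~7 GFLOPs for a 4-channel
    430x560 input); every width is configurable because only the
    textual constraints of the architecture are normative.
    """

    in_channels: int = 4
    stem_channels: int = 48
    expansion_ratio: int = 6
    stage_channels: tuple = (32, 64, 128)
    blocks_per_stage: tuple = (2, 3, 4)
    decoder_channels: tuple = (80, 48, 24)
    skip_policy: str = "noise_block_only"

    def __post_init__(self):
        if self.in_channels not in (3, 4):
            raise ValueError("in_channels must be 3 or 4")
        if len(self.stage_channels) != len(self.blocks_per_stage):
            raise ValueError("stage_channels and blocks_per_stage length mismatch")
        if len(self.decoder_channels) != len(self.stage_channels):
            raise ValueError("decoder_channels must have one entry per stage")
        if list(self.blocks_per_stage) != sorted(self.blocks_per_stage):
            raise ValueError("blocks_per_stage must be non-decreasing with depth")
        if min(self.stage_channels) <= 0 or min(self.decoder_channels) <= 0 \
                or self.stem_channels <= 0 or self.expansion_ratio <= 0:
            raise ValueError("all widths must be positive")
        if self.skip_policy not in ("noise_block_only", "full_unet"):
            raise ValueError(f"unknown skip_policy {self.skip_policy!r}")
        self.stage_channels = tuple(self.stage_channels)
        self.blocks_per_stage = tuple(self.blocks_per_stage)
        self.decoder_channels = tuple(self.decoder_channels)

    @property
    def levels(self) -> int:
        """Number of 2x downsamplings (stem + one per stage)."""
        return 1 + len(self.stage_channels)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(**{k: tuple(v) if isinstance(v, list) else v
                      for k, v in d.items()})


def small_config(in_channels: int = 4) -> NetworkConfig:
    """Reduced-width preset for small images (e.g. 128x128 phantoms)."""
    return NetworkConfig(
        in_channels=in_channels, stem_channels=12, expansion_ratio=2,
        stage_channels=(12, 16), blocks_per_stage=(1, 2),
        decoder_channels=(16, 12))


# ---------------------------------------------------------------------------
# architecture walk shared by the builder and the FLOPs estimator


def _conv_out(h, k, s, p):
    return (h + 2 * p - k) // s + 1


def iter_conv_shapes(cfg: NetworkConfig, input_shape):
    """Yield ``(role, cin, cout, k, stride, groups, out_h, out_w)`` for every
    convolution of the network built from ``cfg``, for a (C,H,W) input."""
    c, h, w = input_shape
    t = cfg.expansion_ratio
    h, w = _conv_out(h, 3, 2, 1), _conv_out(w, 3, 2, 1)
    yield ("stem", c, cfg.stem_channels, 3, 2, 1, h, w)
    nr = cfg.stem_channels // 2
    yield ("noise_dw", cfg.stem_channels, cfg.stem_channels, 3, 1,
           cfg.stem_channels, h, w)
    yield ("noise_pw", cfg.stem_channels, nr, 1, 1, 1, h, w)
    yield ("noise_proj", cfg.stem_channels, nr, 1, 1, 1, h, w)
    sizes = [(h, w)]  # resolution of each encoder skip level
    cin = nr
    for ci, nb in zip(cfg.stage_channels, cfg.blocks_per_stage):
        for b in range(nb):
            s = 2 if b == 0 else 1
            mid = cin * t
            yield ("bneck_expand", cin, mid, 1, 1, 1, h, w)
            if s == 2:
                h, w = _conv_out(h, 3, 2, 1), _conv_out(w, 3, 2, 1)
            yield ("bneck_dw", mid, mid, 3, s, mid, h, w)
            yield ("bneck_reduce", mid, ci, 1, 1, 1, h, w)
            cin = ci
        sizes.append((h, w))
    enc_ch = [nr] + list(cfg.stage_channels)
    for j, dc in enumerate(cfg.decoder_channels):
        h, w = sizes[-2 - j]
        skip_idx = len(cfg.stage_channels) - 1 - j
        if cfg.skip_policy == "full_unet" or skip_idx == 0:
            cin = cin + enc_ch[skip_idx]
        yield ("decoder", cin, dc, 3, 1, 1, h, w)
        cin = dc
    yield ("head", cin, 1, 1, 1, 1, h, w)


def estimate_flops(cfg: NetworkConfig, input_shape) -> float:
    """FLOPs of one forward pass: 2 x multiply-accumulates summed over all
    convolutions at their actual spatial resolutions.  Batch norm,
    activations, biases and upsampling are excluded from the count."""
    total = 0.0
    for (_, cin, cout, k, _s, g, oh, ow) in iter_conv_shapes(cfg, input_shape):
        total += 2.0 * oh * ow * cout * (cin // g) * k * k
    return total


# ---------------------------------------------------------------------------
# modules


class _Bottleneck(nn.Module):
    def __init__(self, cin, cout, t, stride, rng):
        super().__init__()
        mid = cin * t
        self._modules["expand"] = nn.ConvBNAct(cin, mid, 1, rng=rng)
        self._modules["dw"] = nn.ConvBNAct(mid, mid, 3, stride, 1, groups=mid,
                                           rng=rng)
        self._modules["reduce"] = nn.ConvBNAct(mid, cout, 1, rng=rng)
        self.residual = stride == 1 and cin == cout

    def __call__(self, x, training):
        y = self._modules["expand"](x, training)
        y = self._modules["dw"](y, training)
        y = self._modules["reduce"](y, training)
        return nn.add(y, x) if self.residual else y


class SegmentationNet(nn.Module):
    """U-shaped encoder-decoder with a sigmoid defect-probability head."""

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        sc = cfg.stem_channels
        nr = sc // 2
        self._modules["stem"] = nn.ConvBNAct(cfg.in_channels, sc, 3, 2, 1, rng=rng)
        self._modules["noise_dw"] = nn.ConvBNAct(sc, sc, 3, 1, 1, groups=sc, rng=rng)
        self._modules["noise_pw"] = nn.ConvBNAct(sc, nr, 1, rng=rng)
        self._modules["noise_proj"] = nn.Conv2d(sc, nr, 1, rng=rng)
        cin = nr
        self.n_stages = len(cfg.stage_channels)
        for i, (ci, nb) in enumerate(zip(cfg.stage_channels, cfg.blocks_per_stage)):
            for b in range(nb):
                self._modules[f"stage{i}_block{b}"] = _Bottleneck(
                    cin, ci, cfg.expansion_ratio, 2 if b == 0 else 1, rng)
                cin = ci
        enc_ch = [nr] + list(cfg.stage_channels)
        for j, dc in enumerate(cfg.decoder_channels):
            skip_idx = self.n_stages - 1 - j
            extra = enc_ch[skip_idx] if (
                cfg.skip_policy == "full_unet" or skip_idx == 0) else 0
            self._modules[f"decoder{j}"] = nn.ConvBNAct(cin + extra, dc, 3, 1, 1,
                                                        rng=rng)
            cin = dc
        self._modules["head"] = nn.Conv2d(cin, 1, 1, bias=True, rng=rng)

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        """Forward pass, NCHW input -> (N,1,H,W) probability map."""
        cfg = self.cfg
        in_h, in_w = x.shape[2], x.shape[3]
        y = self._modules["stem"](x, training)
        d = self._modules["noise_dw"](y, training)
        d = self._modules["noise_pw"](d, training)
        noise_out = nn.add(d, self._modules["noise_proj"](y))
        feats = [noise_out]
        y = noise_out
        for i, nb in enumerate(cfg.blocks_per_stage):
            for b in range(nb):
                y = self._modules[f"stage{i}_block{b}"](y, training)
            feats.append(y)
        for j in range(self.n_stages):
            target = feats[-2 - j]
            y = nn.upsample_bilinear(y, target.shape[2], target.shape[3])
            skip_idx = self.n_stages - 1 - j
            if cfg.skip_policy == "full_unet" or skip_idx == 0:
                y = nn.concat(y, target, axis=1)
            y = self._modules[f"decoder{j}"](y, training)
        y = self._modules["head"](y)
        y = nn.sigmoid(y)
        return nn.upsample_bilinear(y, in_h, in_w)


def build_network(cfg: NetworkConfig, seed: int = 0) -> SegmentationNet:
    return SegmentationNet(cfg, seed=seed)


# ---------------------------------------------------------------------------
# full-size inference helpers


def pad_to_grid(image: np.ndarray, levels: int):
    """Zero-pad bottom/right so H and W are multiples of ``2**levels``.

    ``image`` is (H,W) or (H,W,C).  Returns ``(padded, (H, W))``; slicing
    with the returned record restores the original size exactly.
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    h, w = image.shape[:2]
    m = 1 << levels
    ph = (-h) % m
    pw = (-w) % m
    pad = [(0, ph), (0, pw)] + [(0, 0)] * (image.ndim - 2)
    return np.pad(image, pad), (h, w)


def crop_to(image: np.ndarray, record) -> np.ndarray:
    h, w = record
    return image[:h, :w]


def predict(net: SegmentationNet, sample) -> np.ndarray:
    """Run the network on one sample at full resolution.

    Pads to the downsampling grid, runs inference (batch-norm running
    statistics), and crops back — no resizing, so defect details are
    preserved.  Returns the (H,W) defect-probability map.
    """
    image = sample.image if hasattr(sample, "image") else np.asarray(sample)
    if image.ndim != 3:
        raise ValueError("expected an (H,W,C) image")
    if image.shape[2] != net.cfg.in_channels:
        raise ValueError(
            f"sample has {image.shape[2]} channels, network expects "
            f"{net.cfg.in_channels}")
    padded, rec = pad_to_grid(image, net.cfg.levels)
    x = Tensor(padded.transpose(2, 0, 1)[None].astype(np.float32))
    prob = net(x, training=False).data[0, 0]
    return crop_to(prob, rec).astype(np.float64)


BINARY_THRESHOLD = 0.5  # canonical cut for turning probabilities into masks


def save_weights(net: SegmentationNet, path):
    """Checkpoint: parameter/buffer arrays with the config embedded."""
    state = net.state_dict()
    state["__config__"] = np.frombuffer(
        yaml.safe_dump(asdict(net.cfg)).encode(), dtype=np.uint8)
    np.savez(path, **state)


def load_weights(path) -> SegmentationNet:
    with np.load(path) as z:
        cfg_yaml = bytes(z["__config__"]).decode()
        d = {k: z[k] for k in z.files if k != "__config__"}
    cfg_d = yaml.safe_load(cfg_yaml)
    cfg = NetworkConfig(**{k: tuple(v) if isinstance(v, list) else v
                           for k, v in cfg_d.items()})
    net = SegmentationNet(cfg)
    net.load_state_dict(d)
    return net
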