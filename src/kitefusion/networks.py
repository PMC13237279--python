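"""Two-branch fusion segmentation architecture.

The model couples two encoder–decoders with complementary receptive fields:

- a **U-shaped branch** whose encoder is a stack of MobileNet-style inverted
  residual blocks, halving the spatial size at each of 4 levels — it captures
  global lesion shape and size;
- a **kite branch** whose encoder *up*-samples (spatial growth) and whose
  decoder pools back down — its receptive field stays concentrated on small
  neighbourhoods, which makes it sensitive to lesion edges.  Because the
  growing encoder is memory-hungry, the kite branch receives a down-scaled
  copy of the input, and its growth factors are capped at (2, 2, 2, 1):
  three spatial doublings followed by a channel-only stage.

Each branch has 4 skip concatenations pairing decoder features with mirrored
encoder features.  The two decoded feature maps are fused by resizing the
kite output up to the U branch's resolution, concatenating along channels,
projecting to per-class maps, resizing to the input size and applying a
per-pixel softmax.  Either branch can be disabled to obtain the single-branch
ablation models.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .nn import (
    Tensor,
    concat,
    Module,
    Conv2d,
    ConvBNReLU,
    InvertedResidual,
)

__all__ = [
    "FusionConfig",
    "FeaturePyramid",
    "SegmentationOutput",
    "UBranch",
    "KiteBranch",
    "FusionModel",
    "build_fusion_model",
    "unet_branch_forward",
    "kite_branch_forward",
    "fuse",
    "fusion_forward",
    "save_checkpoint",
    "load_checkpoint",
]

ENCODER_LEVELS = 4


@dataclass
class FusionConfig:
    input_size: int = 512
    kite_input_size: int = 128
    encoder_levels: int = ENCODER_LEVELS
    u_channels: tuple = (16, 24, 32, 48, 64)
    k_channels: tuple = (8, 8, 8, 8, 8)
    kite_growth: tuple = (2, 2, 2, 1)
    num_classes: int = 2
    upsample_mode: str = "bilinear"
    init_seed: int = 0
    use_unet: bool = True
    use_kite: bool = True

    def __post_init__(self):
        self.u_channels = tuple(self.u_channels)
        self.k_channels = tuple(self.k_channels)
        self.kite_growth = tuple(self.kite_growth)
        if self.encoder_levels != ENCODER_LEVELS:
            raise ValueError(f"encoder_levels is fixed at {ENCODER_LEVELS}")
        for name, ch in (("u_channels", self.u_channels), ("k_channels", self.k_channels)):
            if len(ch) != self.encoder_levels + 1:
                raise ValueError(
                    f"{name} must list {self.encoder_levels + 1} widths, got {len(ch)}"
                )
        if len(self.kite_growth) != self.encoder_levels:
            raise ValueError("kite_growth must have one factor per encoder level")
        if self.kite_input_size > self.input_size:
            raise ValueError("kite_input_size must be <= input_size")
        if self.input_size % 2**self.encoder_levels:
            raise ValueError(
                f"input_size must be divisible by {2**self.encoder_levels}"
            )
        if not (self.use_unet or self.use_kite):
            raise ValueError("at least one branch must be enabled")
        if self.upsample_mode not in ("bilinear", "nearest"):
            raise ValueError(f"unknown upsample_mode {self.upsample_mode!r}")

    @classmethod
    def desk(cls, **overrides) -> "FusionConfig":
        """Reduced profile with the same topology, CPU-trainable."""
        kw = dict(
            input_size=128,
            kite_input_size=16,
            u_channels=(6, 12, 18, 24, 32),
            k_channels=(4, 4, 4, 4, 4),
        )
        kw.update(overrides)
        return cls(**kw)


@dataclass
class FeaturePyramid:
    """Ordered per-level encoder features P1..P5 of one branch."""

    levels: list  # of Tensor

    @property
    def spatial_sizes(self) -> list:
        return [t.shape[2] for t in self.levels]

    @property
    def channel_counts(self) -> list:
        return [t.shape[1] for t in self.levels]


@dataclass
class SegmentationOutput:
    probabilities: Tensor  # (N, num_classes, H, W), per-pixel softmax
    logits: Tensor

    @property
    def foreground(self) -> np.ndarray:
        return self.probabilities.data[:, 1]


class UBranch(Module):
    """Contracting/expanding branch: 4 halving encoder levels, 4 skip concats."""

    def __init__(self, cfg: FusionConfig, rng):
        super().__init__()
        u = cfg.u_channels
        self.mode = cfg.upsample_mode
        self.stem = ConvBNReLU(1, u[0], rng=rng)
        self.encoders = [
            InvertedResidual(u[i], u[i + 1], stride=2, rng=rng) for i in range(4)
        ]
        # decoder stage i consumes concat(Q_i, P_{5-i}) and emits the next Q
        self.decoders = [
            ConvBNReLU(u[4], u[3], rng=rng),
            ConvBNReLU(2 * u[3], u[2], rng=rng),
            ConvBNReLU(2 * u[2], u[1], rng=rng),
            ConvBNReLU(2 * u[1], u[0], rng=rng),
            ConvBNReLU(2 * u[0], u[0], rng=rng),
        ]
        self.out_channels = u[0]

    def encode(self, x: Tensor) -> FeaturePyramid:
        p = self.stem(x)
        levels = [p]
        for enc in self.encoders:
            p = enc(p).relu()
            levels.append(p)
        return FeaturePyramid(levels=levels)

    def __call__(self, x: Tensor):
        pyr = self.encode(x)
        p = pyr.levels
        q = self.decoders[0](p[4])
        for i in range(4):
            skip = p[3 - i]
            q = q.resize(skip.shape[2:], mode=self.mode)
            r = concat([q, skip], axis=1)
            q = self.decoders[i + 1](r)
        return pyr, q  # q at full input resolution


class KiteBranch(Module):
    """Overcomplete branch: encoder up-samples, decoder pools back down."""

    def __init__(self, cfg: FusionConfig, rng):
        super().__init__()
        k = cfg.k_channels
        self.mode = cfg.upsample_mode
        self.growth = cfg.kite_growth
        self.input_size = cfg.kite_input_size
        self.stem = ConvBNReLU(1, k[0], rng=rng)
        self.encoders = [ConvBNReLU(k[i], k[i + 1], rng=rng) for i in range(4)]
        self.decoders = [
            ConvBNReLU(k[4], k[3], rng=rng),
            ConvBNReLU(2 * k[3], k[2], rng=rng),
            ConvBNReLU(2 * k[2], k[1], rng=rng),
            ConvBNReLU(2 * k[1], k[0], rng=rng),
            ConvBNReLU(2 * k[0], k[0], rng=rng),
        ]
        self.out_channels = k[0]

    def encode(self, x: Tensor) -> FeaturePyramid:
        p = self.stem(x)
        levels = [p]
        for enc, g in zip(self.encoders, self.growth):
            p = enc(p)
            if g != 1:
                p = p.resize((p.shape[2] * g, p.shape[3] * g), mode=self.mode)
            levels.append(p)
        return FeaturePyramid(levels=levels)

    def __call__(self, x: Tensor):
        s = self.input_size
        if x.shape[2] != s or x.shape[3] != s:
            raise ValueError(
                f"kite branch expects a {s}x{s} input, got {x.shape[2]}x{x.shape[3]}"
            )
        pyr = self.encode(x)
        p = pyr.levels
        q = self.decoders[0](p[4])
        for i in range(4):
            skip = p[3 - i]
            q = q.resize(skip.shape[2:], mode=self.mode)  # pooling step
            r = concat([q, skip], axis=1)
            q = self.decoders[i + 1](r)
        return pyr, q  # q back at kite input resolution


class FusionModel(Module):
    def __init__(self, config: FusionConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.init_seed)
        self.unet = UBranch(config, rng) if config.use_unet else None
        self.kite = KiteBranch(config, rng) if config.use_kite else None
        head_in = (self.unet.out_channels if self.unet else 0) + (
            self.kite.out_channels if self.kite else 0
        )
        self.head = Conv2d(head_in, config.num_classes, kernel=1, rng=rng)

    def __call__(self, x) -> SegmentationOutput:
        x = Tensor.as_tensor(x)
        cfg = self.config
        if x.shape[2] != cfg.input_size or x.shape[3] != cfg.input_size:
            raise ValueError(
                f"expected {cfg.input_size}x{cfg.input_size} input, "
                f"got {x.shape[2]}x{x.shape[3]}"
            )
        feats = []
        if self.unet is not None:
            _, qu = self.unet(x)
            feats.append(qu)
        if self.kite is not None:
            down = x.resize(
                (cfg.kite_input_size, cfg.kite_input_size), mode=cfg.upsample_mode
            )
            _, qk = self.kite(down)
            feats.append(qk)
        return fuse(feats, self.head, cfg)

    def predict_proba(self, images: np.ndarray, batch_size: int = 8) -> np.ndarray:
        """Foreground-probability maps for (N, H, W) images, in eval mode."""
        self.eval()
        images = np.asarray(images, dtype=np.float32)
        out = []
        for i in range(0, len(images), batch_size):
            batch = images[i : i + batch_size][:, None]
            out.append(self(Tensor(batch)).foreground)
        return np.concatenate(out, axis=0)


def fuse(feats, head: Conv2d, cfg: FusionConfig) -> SegmentationOutput:
    """Resize branch outputs to a common grid, concatenate, project to class
    maps, restore the input resolution and normalize per pixel."""
    target = max(f.shape[2] for f in feats)
    feats = [
        f.resize((target, target), mode=cfg.upsample_mode) if f.shape[2] != target else f
        for f in feats
    ]
    q = concat(feats, axis=1) if len(feats) > 1 else feats[0]
    logits = head(q)
    logits = logits.resize((cfg.input_size, cfg.input_size), mode=cfg.upsample_mode)
    return SegmentationOutput(probabilities=logits.softmax(axis=1), logits=logits)


def build_fusion_model(config: FusionConfig) -> FusionModel:
    """Build the model with parameters reproducibly initialized from
    ``config.init_seed``."""
    return FusionModel(config)


# Thin functional wrappers mirroring the branch-level contract.


def unet_branch_forward(model: FusionModel, image) -> tuple:
    """(FeaturePyramid, decoded full-resolution feature) of the U branch."""
    if model.unet is None:
        raise ValueError("model was built without the U branch")
    return model.unet(Tensor.as_tensor(image))


def kite_branch_forward(model: FusionModel, image) -> tuple:
    """(FeaturePyramid, decoded feature) of the kite branch; the image must
    already be down-scaled to the kite input size."""
    if model.kite is None:
        raise ValueError("model was built without the kite branch")
    return model.kite(Tensor.as_tensor(image))


def fusion_forward(model: FusionModel, image) -> SegmentationOutput:
    return model(image)


# --- checkpoints --------------------------------------------------------------


def save_checkpoint(model: FusionModel, path):
    state = model.state_dict()
    np.savez_compressed(
        path, __config__=np.frombuffer(
            json.dumps(asdict(model.config)).encode(), dtype=np.uint8
        ), **state
    )


def load_checkpoint(path) -> FusionModel:
    with np.load(path) as data:
        cfg_json = bytes(data["__config__"]).decode()
        cfg = FusionConfig(**json.loads(cfg_json))
        model = build_fusion_model(cfg)
        model.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
    return model
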