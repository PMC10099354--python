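"""The three segmentation architectures and their builders.

All three networks share one contract: a (window, window, 3) RGB patch in,
a (window, window) per-pixel microaneurysm probability map out, produced by
a 1x1 two-channel convolution head under a softmax over the two classes
(background, lesion).  The foreground channel is the probability map.

Reference configurations (input 576):

* ``unet`` — five encoder stages of two 3x3 conv + BN + ReLU layers with
  widths 16, 32, 64, 128, 256 and 2x2 max-pooling, a 512-channel bottleneck
  at 18x18, and a mirrored decoder with nearest 2x up-sampling and skip
  concatenations.  About 7.87 M trainable parameters.
* ``resnet34_unet`` — a standard ResNet34 convolutional body as the encoder
  (7x7/2 stem, 3x3/2 max-pool, residual stages of widths 64/128/256/512),
  whose deepest feature at input 576 is 18x18x512; a five-block decoder with
  widths 256/128/64/32/16, additive attention gates on each skip, and the
  raw input image concatenated before the final block.  About 24.6 M
  trainable parameters.
* ``unetpp`` — nested dense skip topology: node X(i,j) consumes the
  up-sampled X(i+1, j-1) concatenated with all X(i, 0..j-1); four
  down-samplings with widths 32/64/128/256/512, optional deep supervision
  averaging 1x1 heads on X(0, 1..4).

Parameter counts are functions of the configuration only, never of the
weights, so the counts are auditable without loading a checkpoint.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np

from . import nn
from .nn import Tensor
from .nn import autograd as ag

ARCHITECTURES = ("unet", "resnet34_unet", "unetpp")

_DEFAULT_BASE_WIDTH = {"unet": 16, "resnet34_unet": 64, "unetpp": 32}
_DEFAULT_DEPTH = {"unet": 5, "resnet34_unet": 5, "unetpp": 4}


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyper-parameters.

    ``depth`` is the number of down-sampling stages; ``base_width`` the
    channel count of the first stage (widths double per stage).  For the
    plain U-Net, ``bottleneck_width`` defaults to ``base_width * 2**depth``
    (512 at the reference configuration).  ``attention_gates`` applies to
    the ResNet34-UNet decoder; ``deep_supervision`` to U-Net++ heads.
    """

    arch: str
    input_size: int = 576
    in_channels: int = 3
    base_width: Optional[int] = None
    depth: Optional[int] = None
    bottleneck_width: Optional[int] = None
    deep_supervision: bool = False
    attention_gates: bool = True
    pretrained_encoder: bool = False

    def __post_init__(self):
        if self.arch not in ARCHITECTURES:
            raise ValueError(f"unknown arch {self.arch!r}; expected one of "
                             f"{ARCHITECTURES}")
        if self.base_width is not None and self.base_width < 1:
            raise ValueError("base_width must be >= 1")

    def resolved(self) -> "ModelConfig":
        """Fill in per-architecture defaults for unset fields."""
        base = self.base_width or _DEFAULT_BASE_WIDTH[self.arch]
        depth = self.depth or _DEFAULT_DEPTH[self.arch]
        if self.arch == "resnet34_unet":
            depth = 5  # fixed by the ResNet34 body (stem/2, pool/2, 3 strided stages)
        bneck = self.bottleneck_width or base * 2 ** depth
        if self.input_size % (2 ** depth) != 0:
            raise ValueError(
                f"input_size {self.input_size} must be divisible by "
                f"2**depth = {2 ** depth} for arch {self.arch}")
        return dataclasses.replace(self, base_width=base, depth=depth,
                                   bottleneck_width=bneck)

    @classmethod
    def reference(cls, arch: str) -> "ModelConfig":
        """The documented full-size configuration for ``arch`` (input 576)."""
        return cls(arch=arch).resolved()


# --------------------------------------------------------------------- U-Net

class UNetNet(nn.Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        widths = [cfg.base_width * 2 ** i for i in range(cfg.depth)]
        self.depth = cfg.depth
        self.encoders = []
        cin = cfg.in_channels
        for w in widths:
            self.encoders.append(nn.DoubleConv(cin, w, rng))
            cin = w
        self.bottleneck = nn.DoubleConv(widths[-1], cfg.bottleneck_width, rng)
        self.decoders = []
        cur = cfg.bottleneck_width
        for w in reversed(widths):
            self.decoders.append(nn.DoubleConv(cur + w, w, rng))
            cur = w
        self.head = nn.Conv2d(widths[0], 2, kernel=1, padding=0, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        skips = []
        for enc in self.encoders:
            x = enc(x)
            skips.append(x)
            x = ag.max_pool2d(x, 2)
        x = self.bottleneck(x)
        for dec, skip in zip(self.decoders, reversed(skips)):
            x = dec(ag.concat([ag.upsample2x(x), skip]))
        return self.head(x)


# ----------------------------------------------------------- ResNet34 + UNet

class ResNet34Encoder(nn.Module):
    """Standard ResNet34 convolutional body emitting multi-scale features."""

    BLOCKS = (3, 4, 6, 3)

    def __init__(self, in_channels: int, base_width: int,
                 rng: np.random.Generator):
        super().__init__()
        w = base_width
        self.stem = nn.Conv2d(in_channels, w, kernel=7, stride=2, padding=3,
                              bias=False, rng=rng)
        self.stem_bn = nn.BatchNorm2d(w)
        self.stages = []
        cin = w
        for s, n_blocks in enumerate(self.BLOCKS):
            cout = w * 2 ** s
            blocks = []
            for b in range(n_blocks):
                stride = 2 if (s > 0 and b == 0) else 1
                blocks.append(nn.ResBlock(cin, cout, rng, stride=stride))
                cin = cout
            self.stages.append(nn.Sequential(*blocks))

    def forward(self, x: Tensor) -> list[Tensor]:
        """Return [stem/2, stage1/4, stage2/8, stage3/16, stage4/32] features."""
        s = ag.relu(self.stem_bn(self.stem(x)))
        f = ag.max_pool2d(s, kernel=3, stride=2, padding=1)
        feats = [s]
        for stage in self.stages:
            f = stage(f)
            feats.append(f)
        return feats


class ResNet34UNetNet(nn.Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        w = cfg.base_width
        self.encoder = ResNet34Encoder(cfg.in_channels, w, rng)
        self.use_attention = cfg.attention_gates
        # the last two stages keep at least 8 channels (or w, if smaller) so
        # scaled-down configs retain usable capacity at full resolution; at
        # the reference width 64 this is exactly 256/128/64/32/16
        floor_w = min(8, w)
        dec_widths = [4 * w, 2 * w, w, max(w // 2, floor_w), max(w // 4, floor_w)]
        skip_chs = [4 * w, 2 * w, w, w, cfg.in_channels]
        self.gates = []
        self.decoders = []
        cur = 8 * w
        for dw, sc in zip(dec_widths, skip_chs):
            if self.use_attention:
                self.gates.append(nn.AttentionGate(sc, cur, rng))
            self.decoders.append(nn.DoubleConv(cur + sc, dw, rng))
            cur = dw
        self.head = nn.Conv2d(dec_widths[-1], 2, kernel=1, padding=0, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        feats = self.encoder(x)
        stem, f1, f2, f3, f4 = feats
        skips = [f3, f2, f1, stem, x]  # x: raw pixels join the final block
        cur = f4
        for i, (dec, skip) in enumerate(zip(self.decoders, skips)):
            cur = ag.upsample2x(cur)
            if self.use_attention:
                skip = self.gates[i](skip, cur)
            cur = dec(ag.concat([cur, skip]))
        return self.head(cur)


# -------------------------------------------------------------------- U-Net++

class UNetPPNet(nn.Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.depth = cfg.depth
        widths = [cfg.base_width * 2 ** i for i in range(cfg.depth + 1)]
        self.widths = widths
        self.deep_supervision = cfg.deep_supervision
        # backbone column X(i, 0)
        self.backbone = []
        cin = cfg.in_channels
        for wdt in widths:
            self.backbone.append(nn.DoubleConv(cin, wdt, rng))
            cin = wdt
        # nested nodes X(i, j), j >= 1, keyed "i_j"
        self.nodes = {}
        node_list = []
        for j in range(1, cfg.depth + 1):
            for i in range(0, cfg.depth + 1 - j):
                cin_node = widths[i] * j + widths[i + 1]
                node = nn.DoubleConv(cin_node, widths[i], rng)
                self.nodes[f"{i}_{j}"] = node
                node_list.append(node)
        self._node_modules = node_list  # for parameter discovery
        n_heads = cfg.depth if cfg.deep_supervision else 1
        self.heads = [nn.Conv2d(widths[0], 2, kernel=1, padding=0, rng=rng)
                      for _ in range(n_heads)]

    def forward(self, x: Tensor) -> Tensor:
        d = self.depth
        grid: dict[tuple[int, int], Tensor] = {}
        cur = x
        for i, enc in enumerate(self.backbone):
            cur = enc(cur)
            grid[(i, 0)] = cur
            if i < d:
                cur = ag.max_pool2d(cur, 2)
        for j in range(1, d + 1):
            for i in range(0, d + 1 - j):
                inputs = [grid[(i, k)] for k in range(j)]
                inputs.append(ag.upsample2x(grid[(i + 1, j - 1)]))
                grid[(i, j)] = self.nodes[f"{i}_{j}"](ag.concat(inputs))
        if self.deep_supervision:
            logits = [head(grid[(0, j)])
                      for j, head in zip(range(1, d + 1), self.heads)]
            out = logits[0]
            for lg in logits[1:]:
                out = ag.add(out, lg)
            return ag.scale(out, 1.0 / len(logits))
        return self.heads[0](grid[(0, d)])


# ------------------------------------------------------------------ SegModel

class SegModel:
    """A built architecture with the patch -> probability-map contract."""

    def __init__(self, config: ModelConfig, net: nn.Module):
        self.config = config
        self.net = net

    @property
    def parameter_count(self) -> int:
        return count_parameters(self)

    def logits(self, batch: Tensor) -> Tensor:
        """Raw two-channel logits for a (N, 3, H, W) tensor (training path)."""
        return self.net(batch)

    def predict_batch(self, patches: np.ndarray) -> np.ndarray:
        """Probability maps for a batch of (N, H, W, 3) RGB patches.

        uint8 input is scaled to [0, 1]; output is (N, H, W) foreground
        probabilities in [0, 1].
        """
        x = as_input_batch(patches)
        h, w = x.shape[2], x.shape[3]
        div = 2 ** self.config.resolved().depth
        if h % div or w % div:
            raise ValueError(f"patch size {h}x{w} not divisible by {div}")
        self.net.eval()
        with ag.no_grad():
            out = self.net(Tensor(x))
        probs = ag.softmax_channel(out.data)[:, 1]
        return probs

    def predict(self, patch: np.ndarray) -> np.ndarray:
        """Probability map for a single (H, W, 3) patch."""
        return self.predict_batch(patch[None])[0]

    def save(self, path: str | Path) -> None:
        """Save weights as .npz with a plain-text JSON config sidecar."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.net.state_dict())
        sidecar = dataclasses.asdict(self.config)
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "SegModel":
        path = Path(path)
        cfg = ModelConfig(**json.loads(path.with_suffix(".json").read_text()))
        model = build_model(cfg)
        state = dict(np.load(path.with_suffix(".npz")))
        model.net.load_state_dict(state)
        return model


def as_input_batch(patches: np.ndarray) -> np.ndarray:
    """(N, H, W, 3) uint8/float RGB -> (N, 3, H, W) float32 in [0, 1]."""
    x = np.asarray(patches)
    if x.ndim != 4 or x.shape[-1] != 3:
        raise ValueError(f"expected (N, H, W, 3) RGB batch, got {x.shape}")
    x = x.astype(np.float32)
    if x.max() > 1.0:
        x = x / 255.0
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


def count_parameters(model: Union[SegModel, nn.Module]) -> int:
    """Total trainable parameter count (weights and biases; BN running
    statistics are buffers and excluded; frozen parameters are excluded)."""
    net = model.net if isinstance(model, SegModel) else model
    return sum(p.data.size for p in net.parameters() if p.requires_grad)


def freeze(module: nn.Module) -> None:
    """Mark every parameter of ``module`` non-trainable."""
    for p in module.parameters():
        p.requires_grad = False


def build_unet(config: ModelConfig, seed: int = 0) -> SegModel:
    """Build the plain U-Net (He-initialized, seeded)."""
    cfg = config.resolved()
    if cfg.arch != "unet":
        raise ValueError(f"build_unet got arch {cfg.arch!r}")
    return SegModel(cfg, UNetNet(cfg, np.random.default_rng(seed)))


def build_resnet34_unet(config: ModelConfig, seed: int = 0) -> SegModel:
    """Build the ResNet34-encoder U-Net with attention-gated skips."""
    cfg = config.resolved()
    if cfg.arch != "resnet34_unet":
        raise ValueError(f"build_resnet34_unet got arch {cfg.arch!r}")
    if cfg.pretrained_encoder:
        raise ValueError(
            "pretrained encoder weights are not bundled; build with "
            "pretrained_encoder=False and load a checkpoint for offline use")
    return SegModel(cfg, ResNet34UNetNet(cfg, np.random.default_rng(seed)))


def build_unetpp(config: ModelConfig, seed: int = 0) -> SegModel:
    """Build the U-Net++ with nested dense skips."""
    cfg = config.resolved()
    if cfg.arch != "unetpp":
        raise ValueError(f"build_unetpp got arch {cfg.arch!r}")
    return SegModel(cfg, UNetPPNet(cfg, np.random.default_rng(seed)))


_BUILDERS = {"unet": build_unet, "resnet34_unet": build_resnet34_unet,
             "unetpp": build_unetpp}


def build_model(config: ModelConfig, seed: int = 0) -> SegModel:
    """Dispatch to the builder matching ``config.arch``."""
    return _BUILDERS[config.arch](config, seed=seed)
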