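"""Network architectures.

Two families live here:

* :class:`MixedUNet` — a U-Net whose encoder embeds a small number of 3D
  convolutions into an otherwise 2D residual trunk.  The network consumes a
  stack of ``k`` adjacent CT slices (treated as a depth axis) and predicts a
  segmentation map for the central slice only.  Each encoder stage ("mixed
  layer") applies one depth-reducing 3D convolution in its first block,
  fuses it with a global pointwise path replicated along depth, folds depth
  into channels (``C' = C x D``) and continues with 2D inverted-bottleneck
  residual blocks.  The stage output concatenates the last block with the
  first block's fused map, doubling the channel count handed to the next
  stage and to the decoder skip.

* :class:`Baseline25DUNet` — the conventional 2.5D alternative: a standard
  residual 2D encoder (18/50/101-layer) whose first convolution is widened
  to ``k`` input channels, with a U-Net decoder.  Adjacent-slice context is
  fused immediately by the first convolution, which is exactly the
  behaviour the mixed architecture is designed to avoid.

Array layout is channel-first throughout: 2D maps are ``(N, C, H, W)``,
3D maps ``(N, C, D, H, W)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .nn import tensor as F
from .nn.modules import (
    Module, Conv2d, Conv3d, BatchNorm2d, BatchNorm3d, Sequential, seed_init,
)
from .nn.tensor import Tensor, as_tensor

__all__ = [
    "MixedNetConfig", "MixedUNet", "Baseline25DUNet",
    "build_mixed_unet", "build_baseline_25d_unet",
    "reshape_3d_to_2d", "reshape_2d_to_3d",
    "count_parameters", "parameter_audit", "forward_central_slice",
    "quarter_width_config", "deeper_config",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class MixedNetConfig:
    """All architecture knobs of the mixed 2D/3D U-Net."""

    in_slices: int = 7
    stem_channels: int = 64
    layer_channels: tuple = (64, 128, 256, 512)
    blocks_per_layer: tuple = (2, 2, 2, 2)
    depth_kernels: tuple = (2, 2, 2, 3)
    expansion: int = 4
    decoder_channels: tuple = (256, 128, 64, 32, 16)
    out_classes: int = 1

    def __post_init__(self):
        if self.in_slices < 1 or self.in_slices % 2 == 0:
            raise ValueError("in_slices must be a positive odd number")
        for name in ("layer_channels", "blocks_per_layer", "depth_kernels"):
            if len(getattr(self, name)) != 4:
                raise ValueError(f"{name} must have 4 entries")
        if len(self.decoder_channels) != 5:
            raise ValueError("decoder_channels must have 5 entries")
        if any(d not in (2, 3) for d in self.depth_kernels):
            raise ValueError("depth kernels must be 2 or 3")
        if any(v < 1 for v in (self.stem_channels, *self.layer_channels,
                               *self.blocks_per_layer, *self.decoder_channels)):
            raise ValueError("all widths and block counts must be positive")
        for d_in, d_out in zip(self.depth_trajectory(), self.depth_trajectory()[1:]):
            if d_out < 1:
                raise ValueError(
                    f"depth axis exhausted: {d_in} slices cannot absorb the "
                    "configured depth kernels")

    def depth_trajectory(self) -> list[int]:
        """Depth of the feature volume entering each stage: stem then layers 1-4."""
        traj = [self.in_slices]
        for d in self.depth_kernels:
            traj.append(traj[-1] - (d - 1))
        return traj

    def to_dict(self) -> dict:
        return asdict(self)


def deeper_config() -> MixedNetConfig:
    """The deeper variant: more residual blocks per stage, all else default."""
    return MixedNetConfig(blocks_per_layer=(9, 12, 8, 3))


def quarter_width_config() -> MixedNetConfig:
    """A quarter-width model for CPU-scale experiments."""
    return MixedNetConfig(stem_channels=16, layer_channels=(16, 32, 64, 128),
                          decoder_channels=(64, 32, 16, 8, 4))


# ---------------------------------------------------------------------------
# depth <-> channel folding
# ---------------------------------------------------------------------------

def reshape_3d_to_2d(x):
    """Fold depth into channels: (N,C,D,H,W) -> (N, C*D, H, W)."""
    x = as_tensor(x)
    n, c, d, h, w = x.shape
    return F.reshape(x, (n, c * d, h, w))


def reshape_2d_to_3d(x, depth: int):
    """Unfold channels into depth: (N, C*D, H, W) -> (N, C, D, H, W)."""
    x = as_tensor(x)
    n, cp, h, w = x.shape
    if cp % depth:
        raise ValueError(f"{cp} channels not divisible by depth {depth}")
    return F.reshape(x, (n, cp // depth, depth, h, w))


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

class ConvBnRelu2d(Module):
    def __init__(self, cin, cout, kernel=3, stride=1, padding=1, groups=1):
        super().__init__()
        self.conv = Conv2d(cin, cout, kernel, stride, padding, groups, bias=False)
        self.bn = BatchNorm2d(cout)

    def forward(self, x):
        return F.relu(self.bn(self.conv(x)))


class MixedFirstBlock(Module):
    """Depth-reducing 3D convolution fused with a replicated pointwise path.

    The local path is a ``d x 3 x 3`` convolution (no depth padding, so the
    depth axis contracts by ``d - 1``).  The global path views the local
    output as 2D (depth folded into channels), applies two 1x1 convolutions
    down to the local channel count, and is broadcast back along depth onto
    the local map — the 3D residual connection.
    """

    def __init__(self, cin, cout, d, stride):
        super().__init__()
        self.d = d
        self.local_conv = Conv3d(cin, cout, (d, 3, 3), (1, stride, stride),
                                 (0, 1, 1), bias=False)
        self.local_bn = BatchNorm3d(cout)
        self.depth_out = None  # set lazily at build via config; informative only
        self._cout = cout
        self.global_conv1 = None  # created on first wiring (needs depth)
        self._wired = False

    def wire(self, depth_in):
        d_out = depth_in - (self.d - 1)
        cp = self._cout * d_out
        self.global_conv1 = Conv2d(cp, self._cout, 1, bias=False)
        self.global_bn1 = BatchNorm2d(self._cout)
        self.global_conv2 = Conv2d(self._cout, self._cout, 1, bias=False)
        self.global_bn2 = BatchNorm2d(self._cout)
        self.depth_out = d_out
        self._wired = True
        return d_out

    def forward(self, x):
        if x.shape[2] < self.d:
            raise ValueError(f"input depth {x.shape[2]} < depth kernel {self.d}")
        local = self.local_bn(self.local_conv(x))
        folded = reshape_3d_to_2d(local)
        g = F.relu(self.global_bn1(self.global_conv1(folded)))
        g = self.global_bn2(self.global_conv2(g))
        n, c, h, w = g.shape
        fused = F.add(local, F.reshape(g, (n, c, 1, h, w)))  # replicate along depth
        return F.relu(fused)


class InvertedResidual2d(Module):
    """1x1 expand -> depthwise 3x3 -> 1x1 project, with identity shortcut.

    The hidden width is ``expansion`` times the stage's 3D channel count,
    which keeps the parameter budget independent of the folded depth.
    """

    def __init__(self, channels, hidden):
        super().__init__()
        self.pw1 = Conv2d(channels, hidden, 1, bias=False)
        self.bn1 = BatchNorm2d(hidden)
        self.dw = Conv2d(hidden, hidden, 3, 1, 1, groups=hidden, bias=False)
        self.bn2 = BatchNorm2d(hidden)
        self.pw2 = Conv2d(hidden, channels, 1, bias=False)
        self.bn3 = BatchNorm2d(channels)

    def forward(self, x):
        y = F.relu(self.bn1(self.pw1(x)))
        y = F.relu(self.bn2(self.dw(y)))
        y = self.bn3(self.pw2(y))
        return F.relu(F.add(x, y))


class MixedLayer(Module):
    """One encoder stage: 3D first block, 2D residual blocks, concat skip."""

    def __init__(self, cin, cout, d, blocks, stride, depth_in, expansion):
        super().__init__()
        self.first = MixedFirstBlock(cin, cout, d, stride)
        self.depth_out = self.first.wire(depth_in)
        self.cp = cout * self.depth_out
        self.blocks = Sequential(*[
            InvertedResidual2d(self.cp, expansion * cout) for _ in range(blocks - 1)
        ])
        self.n_blocks = blocks
        self.out_channels = 2 * self.cp if blocks > 1 else self.cp

    def forward(self, x):
        fused = self.first(x)
        a = reshape_3d_to_2d(fused)
        if self.n_blocks == 1:
            out2d = a
        else:
            b = self.blocks(a)
            out2d = F.concat([b, a], axis=1)
        return out2d, self.depth_out


class DecoderBlock(Module):
    """Nearest upsampling followed by two 3x3 convolutions."""

    def __init__(self, cin, skip, cout):
        super().__init__()
        self.conv1 = ConvBnRelu2d(cin + skip, cout)
        self.conv2 = ConvBnRelu2d(cout, cout)

    def forward(self, x, skip=None):
        x = F.upsample2d_nearest(x, 2)
        if skip is not None:
            x = F.concat([x, skip], axis=1)
        return self.conv2(self.conv1(x))


# ---------------------------------------------------------------------------
# the mixed 2D/3D U-Net
# ---------------------------------------------------------------------------

class MixedUNet(Module):
    def __init__(self, config: MixedNetConfig | None = None):
        super().__init__()
        cfg = config or MixedNetConfig()
        self.config = cfg
        cs = cfg.stem_channels
        self.stem_conv = Conv3d(1, cs, (3, 7, 7), (1, 2, 2), (1, 3, 3), bias=False)
        self.stem_bn = BatchNorm3d(cs)

        traj = cfg.depth_trajectory()
        cin = cs
        strides = (1, 2, 2, 2)
        skip_widths = []
        for i in range(4):
            layer = MixedLayer(cin, cfg.layer_channels[i], cfg.depth_kernels[i],
                               cfg.blocks_per_layer[i], strides[i], traj[i],
                               cfg.expansion)
            setattr(self, f"layer{i + 1}", layer)
            skip_widths.append(layer.out_channels)
            cin = layer.out_channels // layer.depth_out

        dec = cfg.decoder_channels
        ins = [skip_widths[3]] + list(dec[:4])
        skips = [skip_widths[2], skip_widths[1], skip_widths[0], cs, 0]
        self.decoder = Sequential(*[
            DecoderBlock(i, s, o) for i, s, o in zip(ins, skips, dec)
        ])
        self.head = Conv2d(dec[4], cfg.out_classes, 3, 1, 1, bias=True)

    # -- introspection -------------------------------------------------------
    def depth_trajectory(self) -> list[int]:
        return self.config.depth_trajectory()

    # -- forward -------------------------------------------------------------
    def forward(self, x):
        """x: (N, 1, k, H, W) windowed slice stack -> (N, 1, H, W) probabilities."""
        x = as_tensor(x)
        if x.shape[2] != self.config.in_slices:
            raise ValueError(
                f"expected {self.config.in_slices} slices, got {x.shape[2]}")
        if x.shape[3] % 32 or x.shape[4] % 32:
            raise ValueError("slice height and width must be multiples of 32 "
                             "(the encoder halves the plane five times)")
        s = F.relu(self.stem_bn(self.stem_conv(x)))
        skip0 = F.slice_depth(s, self.config.in_slices // 2)  # central slice, H/2
        h = F.maxpool3d_spatial(s, 3, 2, 1)                    # depth kept, H/4
        skips = []
        for i in range(4):
            layer = getattr(self, f"layer{i + 1}")
            out2d, depth = layer(h)
            skips.append(out2d)
            if i < 3:
                h = reshape_2d_to_3d(out2d, depth)
        x2 = skips[3]
        for block, skip in zip(self.decoder.mods,
                               [skips[2], skips[1], skips[0], skip0, None]):
            x2 = block(x2, skip)
        return F.sigmoid(self.head(x2))


def build_mixed_unet(config: MixedNetConfig | None = None, seed: int = 0) -> MixedUNet:
    """Construct a mixed 2D/3D U-Net with deterministic initialisation."""
    seed_init(seed)
    return MixedUNet(config)


# ---------------------------------------------------------------------------
# 2.5D baseline: residual encoder + U-Net decoder
# ---------------------------------------------------------------------------

class BasicBlock(Module):
    def __init__(self, cin, cout, stride=1):
        super().__init__()
        self.conv1 = Conv2d(cin, cout, 3, stride, 1, bias=False)
        self.bn1 = BatchNorm2d(cout)
        self.conv2 = Conv2d(cout, cout, 3, 1, 1, bias=False)
        self.bn2 = BatchNorm2d(cout)
        self.down = None
        if stride != 1 or cin != cout:
            self.down_conv = Conv2d(cin, cout, 1, stride, 0, bias=False)
            self.down_bn = BatchNorm2d(cout)
            self.down = True

    def forward(self, x):
        idt = self.down_bn(self.down_conv(x)) if self.down else x
        y = F.relu(self.bn1(self.conv1(x)))
        y = self.bn2(self.conv2(y))
        return F.relu(F.add(y, idt))


class Bottleneck(Module):
    expansion = 4

    def __init__(self, cin, planes, stride=1):
        super().__init__()
        cout = planes * self.expansion
        self.conv1 = Conv2d(cin, planes, 1, bias=False)
        self.bn1 = BatchNorm2d(planes)
        self.conv2 = Conv2d(planes, planes, 3, stride, 1, bias=False)
        self.bn2 = BatchNorm2d(planes)
        self.conv3 = Conv2d(planes, cout, 1, bias=False)
        self.bn3 = BatchNorm2d(cout)
        self.down = None
        if stride != 1 or cin != cout:
            self.down_conv = Conv2d(cin, cout, 1, stride, 0, bias=False)
            self.down_bn = BatchNorm2d(cout)
            self.down = True

    def forward(self, x):
        idt = self.down_bn(self.down_conv(x)) if self.down else x
        y = F.relu(self.bn1(self.conv1(x)))
        y = F.relu(self.bn2(self.conv2(y)))
        y = self.bn3(self.conv3(y))
        return F.relu(F.add(y, idt))


_RESNET_SPECS = {
    "resnet18": (BasicBlock, (2, 2, 2, 2)),
    "resnet50": (Bottleneck, (3, 4, 6, 3)),
    "resnet101": (Bottleneck, (3, 4, 23, 3)),
}


class ResNetEncoder(Module):
    """Standard 18/50/101-layer residual trunk without the classifier."""

    def __init__(self, backbone: str, in_channels: int):
        super().__init__()
        if backbone not in _RESNET_SPECS:
            raise ValueError(f"unknown backbone {backbone!r}; "
                             f"choose from {sorted(_RESNET_SPECS)}")
        block, counts = _RESNET_SPECS[backbone]
        self.conv1 = Conv2d(in_channels, 64, 7, 2, 3, bias=False)
        self.bn1 = BatchNorm2d(64)
        cin = 64
        widths = (64, 128, 256, 512)
        for i, (planes, n) in enumerate(zip(widths, counts)):
            mods = []
            for j in range(n):
                stride = 2 if (i > 0 and j == 0) else 1
                mods.append(block(cin, planes, stride))
                cin = planes * getattr(block, "expansion", 1)
            setattr(self, f"layer{i + 1}", Sequential(*mods))
        self.out_channels = (64, 64 * block.__dict__.get("expansion", 1) or 64,)
        exp = getattr(block, "expansion", 1)
        self.feature_channels = [64] + [w * exp for w in widths]

    def forward(self, x):
        f0 = F.relu(self.bn1(self.conv1(x)))           # H/2
        h = F.maxpool2d(f0, 3, 2, 1)                   # H/4
        f1 = self.layer1(h)
        f2 = self.layer2(f1)
        f3 = self.layer3(f2)
        f4 = self.layer4(f3)
        return [f0, f1, f2, f3, f4]


class Baseline25DUNet(Module):
    """Adjacent slices enter as channels of a 2D residual encoder."""

    def __init__(self, backbone: str = "resnet18", in_slices: int = 7,
                 decoder_channels=(256, 128, 64, 32, 16)):
        super().__init__()
        if in_slices < 1:
            raise ValueError("in_slices must be positive")
        self.in_slices = in_slices
        self.encoder = ResNetEncoder(backbone, in_slices)
        fc = self.encoder.feature_channels          # [64, c1, c2, c3, c4]
        ins = [fc[4]] + list(decoder_channels[:4])
        skips = [fc[3], fc[2], fc[1], fc[0], 0]
        self.decoder = Sequential(*[
            DecoderBlock(i, s, o) for i, s, o in zip(ins, skips, decoder_channels)
        ])
        self.head = Conv2d(decoder_channels[4], 1, 3, 1, 1, bias=True)

    def forward(self, x):
        """x: (N, k, H, W) -> (N, 1, H, W) probabilities."""
        x = as_tensor(x)
        feats = self.encoder(x)
        h = feats[4]
        for block, skip in zip(self.decoder.mods,
                               [feats[3], feats[2], feats[1], feats[0], None]):
            h = block(h, skip)
        return F.sigmoid(self.head(h))


def build_baseline_25d_unet(backbone: str = "resnet18", in_slices: int = 7,
                            decoder_channels=(256, 128, 64, 32, 16),
                            seed: int = 0) -> Baseline25DUNet:
    seed_init(seed)
    return Baseline25DUNet(backbone, in_slices, decoder_channels)


# ---------------------------------------------------------------------------
# parameter accounting
# ---------------------------------------------------------------------------

def count_parameters(model: Module) -> int:
    """Total number of trainable parameter elements."""
    return model.num_parameters()


def parameter_audit(model: Module) -> pd.DataFrame:
    """Per-submodule parameter counts; the total row equals count_parameters."""
    rows = []
    for name, sub in model._modules.items():
        rows.append({"submodule": name, "parameters": sub.num_parameters()})
    own = sum(p.size for p in model._params.values())
    if own:
        rows.append({"submodule": "(own)", "parameters": own})
    df = pd.DataFrame(rows)
    df.loc[len(df)] = {"submodule": "total", "parameters": int(df["parameters"].sum())}
    return df


def forward_central_slice(model: Module, stack) -> np.ndarray:
    """Predict the probability map for the central slice of one stack.

    ``stack`` is a ``(k, H, W)`` array (or SliceStack-like object with a
    ``slices`` attribute) of windowed intensities.
    """
    arr = np.asarray(getattr(stack, "slices", stack), dtype=np.float32)
    if arr.ndim != 3:
        raise ValueError("expected a (k, H, W) slice stack")
    was_training = model.training
    model.eval()
    if isinstance(model, MixedUNet):
        out = model(arr[None, None])
    else:
        out = model(arr[None])
    model.train(was_training)
    return out.data[0, 0]
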