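"""Atrous-convolution segmentation network for meniscus / CCPR masks.

The architecture is a DeepLabv3-style encoder–decoder: a ResNet50-type
backbone (7×7 stem convolution, max pooling, and four bottleneck blocks with
3, 4, 6 and 3 residual units) whose last two blocks trade stride for dilation
so the encoder runs at output stride 8; an atrous spatial pyramid pooling
(ASPP) module with five parallel branches (a 1×1 convolution, three 3×3
atrous convolutions at configurable rates, and a global-average-pooling
branch restored by bilinear interpolation) concatenated and fused by a 1×1
convolution; and bilinear restoration of the class scores to the input size.
During training an FCN-style auxiliary head on the third block's output
provides a secondary loss, in the spirit of GoogLeNet's auxiliary
classifiers.

An atrous convolution with base kernel ``k0`` and expansion factor ``s``
covers an effective extent of ``s * (k0 - 1) + 1`` pixels
(:func:`atrous_kernel_size`), enlarging the receptive field at constant cost.

Two independently trained instances of the same architecture segment the
tear meniscus and the central corneal-projection ring; only their weights
differ.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .errors import InputError, InvalidArgumentError, InvalidConfigError

__all__ = [
    "NetworkConfig",
    "SegmentationOutput",
    "SegmentationNetwork",
    "atrous_kernel_size",
    "build_network",
    "predict_mask",
    "save_checkpoint",
    "load_checkpoint",
]

#: Residual units per backbone block (ResNet50 layout).
BLOCK_DEPTHS = (3, 4, 6, 3)


def atrous_kernel_size(k0: int, s: int) -> int:
    """Effective kernel extent of an atrous convolution: ``s * (k0 - 1) + 1``.

    ``k0`` is the base (odd) kernel size and ``s`` the expansion factor; a
    3×3 kernel expanded by 2 covers 5×5 pixels.
    """
    if not (isinstance(k0, (int, np.integer)) and isinstance(s, (int, np.integer))):
        raise InvalidArgumentError("k0 and s must be integers")
    if k0 < 1 or k0 % 2 == 0:
        raise InvalidArgumentError(f"k0 must be odd and positive, got {k0}")
    if s < 1:
        raise InvalidArgumentError(f"expansion factor must be >= 1, got {s}")
    return int(s) * (int(k0) - 1) + 1


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    ``base_channels`` scales every layer width together (64 reproduces the
    standard ResNet50 widths: bottleneck outputs 256/512/1024/2048); smaller
    values give the same topology at desk scale.  ``output_stride`` is fixed
    at 8 by the dilation pattern: blocks 3 and 4 keep stride 1 and dilate by
    ``block3_dilation`` and ``block4_dilation * multi_grid[i]`` respectively.

    ``logit_scale`` is a fixed output multiplier on the class projections
    (main and auxiliary).  At the standard width the conventional value 1 is
    appropriate; width-reduced models train at learning rates tuned for the
    full-width model only if the output multiplier grows as the width
    shrinks (the usual scale-aware parameterisation argument), so desk-scale
    configurations pair ``base_channels < 64`` with a larger ``logit_scale``.
    """

    num_classes: int = 2
    output_stride: int = 8
    block3_dilation: int = 2
    block4_dilation: int = 4
    multi_grid: tuple[int, int, int] = (1, 1, 1)
    aspp_rates: tuple[int, int, int] = (12, 24, 36)
    aspp_channels: int = 256
    aux_head: bool = True
    aux_weight: float = 0.4
    base_channels: int = 64
    logit_scale: float = 1.0

    def validate(self) -> None:
        if self.num_classes < 2:
            raise InvalidConfigError("num_classes must be >= 2")
        if self.output_stride != 8:
            raise InvalidConfigError(
                "this architecture realises output stride 8 only (blocks 3 "
                "and 4 are dilated, not strided)"
            )
        if len(self.multi_grid) != 3:
            raise InvalidConfigError("multi_grid needs exactly 3 entries "
                                     "(the last block has 3 bottlenecks)")
        if len(self.aspp_rates) != 3:
            raise InvalidConfigError("aspp_rates needs exactly 3 entries")
        dils = (self.block3_dilation, self.block4_dilation, *self.multi_grid,
                *self.aspp_rates)
        if any(d < 1 for d in dils):
            raise InvalidConfigError("all dilations/rates must be >= 1")
        if self.aspp_channels < 1 or self.base_channels < 1:
            raise InvalidConfigError("channel counts must be >= 1")
        if self.logit_scale <= 0:
            raise InvalidConfigError("logit_scale must be positive")
        if not 0.0 <= self.aux_weight:
            raise InvalidConfigError("aux_weight must be nonnegative")


@dataclass(frozen=True)
class SegmentationOutput:
    """Per-pixel class scores at input resolution."""

    main_scores: np.ndarray  # (N, num_classes, H, W)
    aux_scores: np.ndarray | None = None  # training mode only


class _Bottleneck(nn.Module):
    """ResNet bottleneck: 1×1 → 3×3 (stride/dilation) → 1×1, residual add.

    A 1×1 projection on the shortcut aligns channels/stride when needed
    (bottleneck1 in the two-variant naming); otherwise the shortcut is the
    identity (bottleneck2).
    """

    def __init__(self, cin, mid, cout, stride, dilation, rng):
        super().__init__()
        self.conv1 = self.add(nn.Conv2d(cin, mid, 1, rng=rng))
        self.bn1 = self.add(nn.BatchNorm2d(mid))
        self.conv2 = self.add(nn.Conv2d(mid, mid, 3, stride=stride,
                                        dilation=dilation, rng=rng))
        self.bn2 = self.add(nn.BatchNorm2d(mid))
        self.conv3 = self.add(nn.Conv2d(mid, cout, 1, rng=rng))
        self.bn3 = self.add(nn.BatchNorm2d(cout))
        self.relu1, self.relu2, self.relu_out = (
            self.add(nn.ReLU()), self.add(nn.ReLU()), self.add(nn.ReLU())
        )
        self.down_conv = self.down_bn = None
        if stride != 1 or cin != cout:
            self.down_conv = self.add(nn.Conv2d(cin, cout, 1, stride=stride, rng=rng))
            self.down_bn = self.add(nn.BatchNorm2d(cout))
        # zero-init of the residual branch's last BN scale: each unit starts
        # as (a projection of) the identity, which preserves low-level
        # contrast through the deep stack and conditions early training
        self.bn3.gamma.data[...] = 0.0

    def forward(self, x, train=False):
        out = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        out = self.relu2.forward(self.bn2.forward(self.conv2.forward(out, train), train), train)
        out = self.bn3.forward(self.conv3.forward(out, train), train)
        if self.down_conv is not None:
            identity = self.down_bn.forward(self.down_conv.forward(x, train), train)
        else:
            identity = x
        return self.relu_out.forward(out + identity, train)

    def backward(self, grad):
        g = self.relu_out.backward(grad)
        gb = self.conv1.backward(self.bn1.backward(self.relu1.backward(
            self.conv2.backward(self.bn2.backward(self.relu2.backward(
                self.conv3.backward(self.bn3.backward(g))
            )))
        )))
        if self.down_conv is not None:
            gs = self.down_conv.backward(self.down_bn.backward(g))
        else:
            gs = g
        return gb + gs


class _ConvBNReLU(nn.Module):
    def __init__(self, cin, cout, k, dilation, rng):
        super().__init__()
        self.conv = self.add(nn.Conv2d(cin, cout, k, dilation=dilation, rng=rng))
        self.bn = self.add(nn.BatchNorm2d(cout))
        self.relu = self.add(nn.ReLU())

    def forward(self, x, train=False):
        return self.relu.forward(self.bn.forward(self.conv.forward(x, train), train), train)

    def backward(self, grad):
        return self.conv.backward(self.bn.backward(self.relu.backward(grad)))


class _ASPP(nn.Module):
    """Five-branch atrous spatial pyramid pooling with 1×1 fusion."""

    def __init__(self, cin, channels, rates, rng):
        super().__init__()
        self.branch1 = self.add(_ConvBNReLU(cin, channels, 1, 1, rng))
        self.atrous = [
            self.add(_ConvBNReLU(cin, channels, 3, r, rng)) for r in rates
        ]
        self.pool = self.add(nn.GlobalAvgPool())
        self.pool_conv = self.add(_ConvBNReLU(cin, channels, 1, 1, rng))
        self.pool_up = self.add(nn.BilinearResize())
        self.fuse = self.add(_ConvBNReLU(5 * channels, channels, 1, 1, rng))
        self.channels = channels

    def forward(self, x, train=False):
        hw = x.shape[2:]
        outs = [self.branch1.forward(x, train)]
        outs += [b.forward(x, train) for b in self.atrous]
        pooled = self.pool_conv.forward(self.pool.forward(x, train), train)
        outs.append(self.pool_up.forward(pooled, out_hw=hw, train=train))
        cat = np.concatenate(outs, axis=1)
        return self.fuse.forward(cat, train)

    def backward(self, grad):
        g = self.fuse.backward(grad)
        c = self.channels
        parts = [g[:, i * c : (i + 1) * c] for i in range(5)]
        gx = self.branch1.backward(np.ascontiguousarray(parts[0]))
        for b, p in zip(self.atrous, parts[1:4]):
            gx += b.backward(np.ascontiguousarray(p))
        gp = self.pool_up.backward(np.ascontiguousarray(parts[4]))
        gx += self.pool.backward(self.pool_conv.backward(gp))
        return gx


class _FCNHead(nn.Module):
    """Auxiliary head: 3×3 conv → dropout → 1×1 conv to class scores."""

    def __init__(self, cin, num_classes, rng, dropout=0.1):
        super().__init__()
        self.block = self.add(_ConvBNReLU(cin, max(cin // 4, num_classes), 3, 1, rng))
        self.drop = self.add(nn.Dropout(dropout))
        self.cls = self.add(nn.Conv2d(max(cin // 4, num_classes), num_classes, 1,
                                      bias=True, rng=rng))

    def forward(self, x, train=False):
        return self.cls.forward(self.drop.forward(self.block.forward(x, train), train), train)

    def backward(self, grad):
        return self.block.backward(self.drop.backward(self.cls.backward(grad)))


class SegmentationNetwork(nn.Module):
    """The full segmentation model; see the module docstring."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        super().__init__()
        config.validate()
        self.config = config
        rng = np.random.default_rng(seed)
        w = config.base_channels
        self.stem_conv = self.add(nn.Conv2d(3, w, 7, stride=2, rng=rng))
        self.stem_bn = self.add(nn.BatchNorm2d(w))
        self.stem_relu = self.add(nn.ReLU())
        self.pool = self.add(nn.MaxPool2d(3, 2, 1))

        def make_block(cin, mid, cout, depth, stride, dilations):
            units = []
            for i in range(depth):
                units.append(
                    self.add(_Bottleneck(cin if i == 0 else cout, mid, cout,
                                         stride if i == 0 else 1,
                                         dilations[i], rng))
                )
            return units

        d3 = config.block3_dilation
        d4 = [config.block4_dilation * m for m in config.multi_grid]
        self.block1 = make_block(w, w, 4 * w, BLOCK_DEPTHS[0], 1, [1] * 3)
        self.block2 = make_block(4 * w, 2 * w, 8 * w, BLOCK_DEPTHS[1], 2, [1] * 4)
        self.block3 = make_block(8 * w, 4 * w, 16 * w, BLOCK_DEPTHS[2], 1, [d3] * 6)
        self.block4 = make_block(16 * w, 8 * w, 32 * w, BLOCK_DEPTHS[3], 1, d4)

        self.aspp = self.add(_ASPP(32 * w, config.aspp_channels,
                                   config.aspp_rates, rng))
        self.classifier = self.add(nn.Conv2d(config.aspp_channels,
                                             config.num_classes, 1,
                                             bias=True, rng=rng))
        self.upsample = self.add(nn.BilinearResize())
        self.aux = None
        self.aux_up = None
        if config.aux_head:
            self.aux = self.add(_FCNHead(16 * w, config.num_classes, rng))
            self.aux_up = self.add(nn.BilinearResize())
        # final per-class projections start at zero: the untrained model
        # emits the maximum-entropy (all-tie) prediction, which also makes
        # early optimisation well-conditioned at small learning rates
        self.classifier.weight.data[...] = 0.0
        if self.aux is not None:
            self.aux.cls.weight.data[...] = 0.0
        self._input_hw = None

    # -- forward / backward -------------------------------------------------

    def backbone(self, x: np.ndarray, train: bool = False):
        """Backbone features: returns (block3 output, block4 output)."""
        h = self.stem_relu.forward(
            self.stem_bn.forward(self.stem_conv.forward(x, train), train), train
        )
        h = self.pool.forward(h, train)
        for u in self.block1:
            h = u.forward(h, train)
        for u in self.block2:
            h = u.forward(h, train)
        for u in self.block3:
            h = u.forward(h, train)
        c3 = h
        for u in self.block4:
            h = u.forward(h, train)
        return c3, h

    def forward(self, x: np.ndarray, train: bool = False) -> SegmentationOutput:
        x = np.ascontiguousarray(x, dtype=nn._F32)
        if x.ndim != 4 or x.shape[1] != 3:
            raise InputError(f"expected (N, 3, H, W) input, got {x.shape}")
        hw = x.shape[2:]
        self._input_hw = hw
        s = np.float32(self.config.logit_scale)
        c3, c4 = self.backbone(x, train)
        feats = self.aspp.forward(c4, train)
        scores = self.classifier.forward(feats, train) * s
        main = self.upsample.forward(scores, out_hw=hw, train=train)
        aux = None
        if train and self.aux is not None:
            aux = self.aux_up.forward(self.aux.forward(c3, train) * s,
                                      out_hw=hw, train=train)
        return SegmentationOutput(main_scores=main, aux_scores=aux)

    def backward(self, grad_main: np.ndarray, grad_aux: np.ndarray | None = None):
        s = np.float32(self.config.logit_scale)
        g = self.classifier.backward(self.upsample.backward(grad_main) * s)
        g = self.aspp.backward(g)
        for u in reversed(self.block4):
            g = u.backward(g)
        if grad_aux is not None and self.aux is not None:
            g = g + self.aux.backward(self.aux_up.backward(grad_aux) * s)
        for u in reversed(self.block3):
            g = u.backward(g)
        for u in reversed(self.block2):
            g = u.backward(g)
        for u in reversed(self.block1):
            g = u.backward(g)
        g = self.pool.backward(g)
        g = self.stem_conv.backward(self.stem_bn.backward(self.stem_relu.backward(g)))
        return g

    def reseed_dropout(self, seed: int) -> None:
        """Make dropout draws reproducible for a training run."""
        i = 0
        stack = [self]
        while stack:
            m = stack.pop()
            if isinstance(m, nn.Dropout):
                m.rng = np.random.default_rng((seed, i))
                i += 1
            stack.extend(getattr(m, "_mods", []))


def build_network(config: NetworkConfig, seed: int = 0) -> SegmentationNetwork:
    """Construct a randomly initialised network (He fan-out init, seeded)."""
    return SegmentationNetwork(config, seed=seed)


def _to_nchw(images: np.ndarray) -> np.ndarray:
    arr = np.asarray(images, dtype=np.float32)
    if arr.ndim == 3:
        arr = arr[None]
    if arr.ndim != 4 or arr.shape[-1] != 3:
        raise InputError(f"expected H×W×3 image(s), got shape {arr.shape}")
    return np.ascontiguousarray(arr.transpose(0, 3, 1, 2))


def normalize_image(images: np.ndarray) -> np.ndarray:
    """Training-time intensity normalisation: centre [0, 1] values at zero."""
    return np.asarray(images, dtype=np.float32) - np.float32(0.5)


def predict_mask(network: SegmentationNetwork, image: np.ndarray) -> np.ndarray:
    """Segment one image (H×W×3) or a batch (N×H×W×3) into binary mask(s).

    Scores tie-break to the lower class index, so an all-zero score map
    predicts background everywhere.
    """
    batched = np.asarray(image).ndim == 4
    x = normalize_image(_to_nchw(image))
    out = network.forward(x, train=False)
    masks = out.main_scores.argmax(axis=1).astype(np.uint8)
    return masks if batched else masks[0]


# -- checkpointing ----------------------------------------------------------


def save_checkpoint(network: SegmentationNetwork, path) -> None:
    """Serialise weights, BN statistics and the config into one ``.npz``."""
    arrays = {f"p{i}": p.data for i, p in enumerate(network.parameters())}
    arrays.update({f"b{i}": b for i, b in enumerate(network.buffers())})
    cfg = asdict(network.config)
    np.savez_compressed(path, __config__=np.frombuffer(
        json.dumps(cfg).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> SegmentationNetwork:
    """Rebuild a network from a checkpoint written by :func:`save_checkpoint`."""
    with np.load(path) as data:
        cfg_json = bytes(data["__config__"]).decode()
        cfg_dict = json.loads(cfg_json)
        for k in ("multi_grid", "aspp_rates"):
            cfg_dict[k] = tuple(cfg_dict[k])
        net = SegmentationNetwork(NetworkConfig(**cfg_dict))
        params = net.parameters()
        for i, p in enumerate(params):
            arr = data[f"p{i}"]
            if arr.shape != p.data.shape:
                raise InputError("checkpoint does not match the architecture")
            p.data[...] = arr
        for i, b in enumerate(net.buffers()):
            b[...] = data[f"b{i}"]
    return net
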