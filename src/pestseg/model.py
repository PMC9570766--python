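"""The attention-augmented nested encoder-decoder segmentation network.

The architecture couples a split-attention residual encoder with the nested
dense-skip decoder of UNet++.  Encoder stages X^{i,0} (i = 0..4) sit at
strides 2, 4, 8, 16, 32; decoder nodes X^{i,j} (j >= 1) concatenate all
same-level predecessors with the 2x-upsampled deeper node, apply a 3x3
convolution to the level width and finish with a spatial/channel
squeeze-excitation (scSE) block.  Deep supervision attaches a 1x1
convolution + sigmoid head to every X^{0,j}; the final probability map is
the mean of the heads (configurable).

Two encoder flavours are provided: a slim split-attention trunk that emits
the decoder widths (default 16, 32, 64, 128, 256) directly, and a
ResNeSt-style bottleneck trunk (natively 64..2048 channels wide, radix 2)
followed by per-stage 1x1 lateral projections to the decoder widths, which
can ingest published ImageNet weights via `adapt_pretrained_stem`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .nn import Tensor, concat, maximum

ATTENTION_VARIANTS = ("scse", "cse", "sse", "none")
ENCODER_VARIANTS = ("slim-split-attn", "resnest-projected")


@dataclass(frozen=True)
class SplitAttentionSpec:
    radix: int = 2
    cardinality: int = 1
    reduction: int = 4

    def __post_init__(self):
        if self.radix < 1 or self.cardinality < 1 or self.reduction < 1:
            raise ValueError("radix, cardinality and reduction must be >= 1")


@dataclass
class ModelConfig:
    in_channels: int = 24
    n_classes: int = 3
    decoder_widths: tuple = (16, 32, 64, 128, 256)
    attention: str = "scse"
    encoder: str = "slim-split-attn"
    head_activation: str = "sigmoid"
    deep_supervision_combine: str = "mean"
    radix: int = 2
    cardinality: int = 1
    attn_reduction: int = 4
    scse_reduction: int = 2
    scse_combine: str = "max"
    trunk_depths: tuple = (3, 4, 23, 3)   # resnest-projected only

    def __post_init__(self):
        self.decoder_widths = tuple(int(w) for w in self.decoder_widths)
        self.trunk_depths = tuple(int(d) for d in self.trunk_depths)
        if len(self.decoder_widths) != 5:
            raise ValueError("decoder_widths must list 5 stage widths")
        if any(a >= b for a, b in zip(self.decoder_widths,
                                      self.decoder_widths[1:])):
            raise ValueError("decoder_widths must be strictly increasing")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.attention not in ATTENTION_VARIANTS:
            raise ValueError(f"attention must be one of {ATTENTION_VARIANTS}")
        if self.encoder not in ENCODER_VARIANTS:
            raise ValueError(f"encoder must be one of {ENCODER_VARIANTS}")
        if self.head_activation not in ("sigmoid", "softmax"):
            raise ValueError("head_activation must be 'sigmoid' or 'softmax'")
        if self.deep_supervision_combine not in ("mean", "last"):
            raise ValueError("deep_supervision_combine must be 'mean' or 'last'")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "ModelConfig":
        d = json.loads(s)
        for k in ("decoder_widths", "trunk_depths"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


# ------------------------------------------------------------------- blocks

class ConvBnRelu(nn.Module):
    def __init__(self, cin, cout, k=3, stride=1, rng=None):
        super().__init__()
        self.conv = nn.Conv2d(cin, cout, k, stride=stride, padding=k // 2,
                              bias=False, rng=rng)
        self.bn = nn.BatchNorm2d(cout)

    def forward(self, x):
        return self.bn(self.conv(x)).relu()


class SplitAttentionBlock(nn.Module):
    """Residual unit with radix-wise branch attention.

    The input is transformed by a grouped 3x3 convolution into `radix`
    branches, the branch sum is globally pooled and passed through a
    two-layer gate whose output (r-softmax across branches; plain sigmoid at
    radix 1) weights the branches before fusion; a shortcut of the block
    input is added and the sum rectified.
    """

    def __init__(self, cin, cout, spec: SplitAttentionSpec = SplitAttentionSpec(),
                 stride=1, rng=None, residual=True):
        super().__init__()
        r, card = spec.radix, spec.cardinality
        groups = r * card
        if cin % groups or cout % groups:
            raise ValueError(
                f"channels in={cin}/out={cout} not divisible by "
                f"radix*cardinality={groups}"
            )
        self.radix = r
        self.cout = cout
        self.residual = residual
        self.probe_uniform_gate = False
        self.conv = nn.Conv2d(cin, cout * r, 3, stride=stride, padding=1,
                              groups=groups, bias=False, rng=rng)
        self.bn = nn.BatchNorm2d(cout * r)
        inter = max(cout // spec.reduction, 4)
        self.fc1 = nn.Conv2d(cout, inter, 1, rng=rng)
        self.fc_bn = nn.BatchNorm2d(inter)
        self.fc2 = nn.Conv2d(inter, cout * r, 1, rng=rng)
        if residual:
            if stride != 1 or cin != cout:
                self.short_conv = nn.Conv2d(cin, cout, 1, stride=stride,
                                            bias=False, rng=rng)
                self.short_bn = nn.BatchNorm2d(cout)
            else:
                self.short_conv = None

    def forward(self, x):
        u = self.bn(self.conv(x)).relu()       # (N, cout*radix, H', W')
        n, _, h, w = u.shape
        r, c = self.radix, self.cout
        ur = u.reshape(n, r, c, h, w)
        usum = ur.sum(axis=1)                   # (N, c, H', W')
        gap = usum.global_avg_pool()            # (N, c, 1, 1)
        gate = self.fc2(self.fc_bn(self.fc1(gap)).relu())  # (N, c*r, 1, 1)
        gr = gate.reshape(n, r, c, 1, 1)
        if self.probe_uniform_gate:
            att = Tensor(np.full((n, r, c, 1, 1), 1.0 / r,
                                 dtype=u.data.dtype))
        elif r == 1:
            att = gr.sigmoid()
        else:
            att = gr.softmax(axis=1)
        v = (ur * att).sum(axis=1)              # (N, c, H', W')
        if not self.residual:
            return v.relu()
        if self.short_conv is not None:
            shortcut = self.short_bn(self.short_conv(x))
        else:
            shortcut = x
        return (v + shortcut).relu()


class SCSE(nn.Module):
    """Concurrent spatial (sSE) and channel (cSE) squeeze-excitation.

    cSE: global-average-pooled channel descriptor -> bottleneck -> sigmoid
    channel weights.  sSE: 1x1 projection to one channel -> sigmoid spatial
    weights.  The two rescaled maps are combined elementwise (max by
    default).  Variants 'cse', 'sse' and 'none' support ablations; the
    `probe_identity` flag forces all gates to 1, reducing every variant to
    the identity.
    """

    def __init__(self, channels, reduction=2, variant="scse", combine="max",
                 rng=None):
        super().__init__()
        if variant not in ATTENTION_VARIANTS:
            raise ValueError(f"unknown attention variant {variant!r}")
        self.variant = variant
        self.combine = combine
        self.probe_identity = False
        if variant in ("scse", "cse"):
            hidden = max(channels // reduction, 1)
            self.cse_fc1 = nn.Conv2d(channels, hidden, 1, rng=rng)
            self.cse_fc2 = nn.Conv2d(hidden, channels, 1, rng=rng)
        if variant in ("scse", "sse"):
            self.sse_conv = nn.Conv2d(channels, 1, 1, rng=rng)

    def forward(self, x):
        if self.variant == "none" or self.probe_identity:
            return x
        parts = []
        if self.variant in ("scse", "cse"):
            g = self.cse_fc2(self.cse_fc1(x.global_avg_pool()).relu()).sigmoid()
            parts.append(x * g)
        if self.variant in ("scse", "sse"):
            s = self.sse_conv(x).sigmoid()
            parts.append(x * s)
        if len(parts) == 1:
            return parts[0]
        if self.combine == "max":
            return maximum(parts[0], parts[1])
        return parts[0] + parts[1]


# ----------------------------------------------------------------- encoders

class SlimSplitAttnEncoder(nn.Module):
    """Reduced split-attention trunk emitting the decoder widths directly."""

    def __init__(self, in_channels, widths, spec, rng):
        super().__init__()
        self.stem = ConvBnRelu(in_channels, widths[0], k=3, stride=2, rng=rng)
        self.stages = nn.ModuleList(
            SplitAttentionBlock(widths[i - 1], widths[i], spec, stride=2, rng=rng)
            for i in range(1, 5)
        )

    def forward(self, x):
        feats = [self.stem(x)]
        for stage in self.stages:
            feats.append(stage(feats[-1]))
        return feats


class ResNeStBottleneck(nn.Module):
    """Bottleneck residual block with a split-attention 3x3 core (expansion 4)."""

    def __init__(self, cin, base, spec, stride=1, rng=None):
        super().__init__()
        cout = base * 4
        self.reduce = ConvBnRelu(cin, base, k=1, rng=rng)
        self.splat = SplitAttentionBlock(base, base, spec, stride=stride,
                                         rng=rng, residual=False)
        self.expand_conv = nn.Conv2d(base, cout, 1, bias=False, rng=rng)
        self.expand_bn = nn.BatchNorm2d(cout)
        if stride != 1 or cin != cout:
            self.short_conv = nn.Conv2d(cin, cout, 1, stride=stride,
                                        bias=False, rng=rng)
            self.short_bn = nn.BatchNorm2d(cout)
        else:
            self.short_conv = None

    def forward(self, x):
        y = self.expand_bn(self.expand_conv(self.splat(self.reduce(x))))
        shortcut = x if self.short_conv is None else self.short_bn(self.short_conv(x))
        return (y + shortcut).relu()


class ResNeStProjectedEncoder(nn.Module):
    """ResNeSt-style trunk + 1x1 lateral projections to the decoder widths.

    Trunk stage widths are the conventional 64 (stem) and 256/512/1024/2048
    (bottleneck stages, radix 2); stage depths default to the 101-layer
    configuration (3, 4, 23, 3).  A 1x1 projection after the stem and each
    stage maps the trunk features onto the requested decoder widths so the
    nested decoder is identical across encoder flavours.
    """

    STEM_WIDTH = 64
    STAGE_BASES = (64, 128, 256, 512)

    def __init__(self, in_channels, widths, spec, rng, depths=(3, 4, 23, 3)):
        super().__init__()
        self.stem_a = ConvBnRelu(in_channels, 32, k=3, stride=2, rng=rng)
        self.stem_b = ConvBnRelu(32, self.STEM_WIDTH, k=3, rng=rng)
        self.stages = nn.ModuleList()
        cin = self.STEM_WIDTH
        for base, depth in zip(self.STAGE_BASES, depths):
            blocks = nn.ModuleList()
            for b in range(depth):
                blocks.append(ResNeStBottleneck(
                    cin, base, spec, stride=2 if b == 0 else 1, rng=rng))
                cin = base * 4
            self.stages.append(_Sequential(blocks))
        trunk_widths = (self.STEM_WIDTH,) + tuple(b * 4 for b in self.STAGE_BASES)
        self.laterals = nn.ModuleList(
            nn.Conv2d(tw, w, 1, rng=rng) for tw, w in zip(trunk_widths, widths)
        )

    def forward(self, x):
        feats = [self.stem_b(self.stem_a(x))]
        for stage in self.stages:
            feats.append(stage(feats[-1]))
        return [lat(f) for lat, f in zip(self.laterals, feats)]


class _Sequential(nn.Module):
    def __init__(self, modules):
        super().__init__()
        self.items = nn.ModuleList(modules)

    def forward(self, x):
        for m in self.items:
            x = m(x)
        return x


def adapt_pretrained_stem(rgb_weight: np.ndarray, target_channels: int) -> np.ndarray:
    """Adapt a pretrained 3-channel stem kernel to C input channels.

    The mean of the RGB kernels is tiled across the C channels and rescaled
    by 3/C, so the pre-activation response to a spatially constant input is
    preserved exactly.
    """
    rgb_weight = np.asarray(rgb_weight)
    if rgb_weight.ndim != 4 or rgb_weight.shape[1] != 3:
        raise ValueError(f"expected (out, 3, kh, kw) weights, got {rgb_weight.shape}")
    if target_channels == 3:
        return rgb_weight.copy()
    mean = rgb_weight.mean(axis=1, keepdims=True)
    return np.repeat(mean * (3.0 / target_channels), target_channels, axis=1)


# -------------------------------------------------------------------- model

class DecoderNode(nn.Module):
    def __init__(self, in_total, width, cfg: ModelConfig, rng):
        super().__init__()
        self.conv = ConvBnRelu(in_total, width, k=3, rng=rng)
        self.att = SCSE(width, reduction=cfg.scse_reduction,
                        variant=cfg.attention, combine=cfg.scse_combine, rng=rng)

    def forward(self, inputs):
        return self.att(self.conv(concat(inputs, axis=1)))


class RsprUnetPP(nn.Module):
    """Nested-decoder segmentation network with split-attention encoder."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        spec = SplitAttentionSpec(cfg.radix, cfg.cardinality, cfg.attn_reduction)
        w = cfg.decoder_widths
        if cfg.encoder == "slim-split-attn":
            self.encoder = SlimSplitAttnEncoder(cfg.in_channels, w, spec, rng)
        else:
            self.encoder = ResNeStProjectedEncoder(
                cfg.in_channels, w, spec, rng, depths=cfg.trunk_depths)
        # decoder nodes X^{i,j}, j >= 1, i + j <= 4; inputs are
        # X^{i,0..j-1} plus the upsampled X^{i+1,j-1}
        self.nodes = {}
        node_list = nn.ModuleList()
        for j in range(1, 5):
            for i in range(0, 5 - j):
                in_total = j * w[i] + w[i + 1]
                node = DecoderNode(in_total, w[i], cfg, rng)
                self.nodes[(i, j)] = node
                node_list.append(node)
        self.node_list = node_list
        self.heads = nn.ModuleList(
            nn.Conv2d(w[0], cfg.n_classes, 1, rng=rng) for _ in range(4)
        )

    def forward(self, x):
        """Return dict with per-head probability maps and the combined map."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        n, c, h, wd = x.shape
        if c != self.cfg.in_channels:
            raise ValueError(
                f"input has {c} channels; model expects {self.cfg.in_channels}"
            )
        if h % 32 or wd % 32:
            raise ValueError(
                f"input {h}x{wd} not divisible by 32; pad the tile first"
            )
        feats = self.encoder(x)
        grid = {(i, 0): f for i, f in enumerate(feats)}
        for j in range(1, 5):
            for i in range(0, 5 - j):
                ins = [grid[(i, k)] for k in range(j)]
                ins.append(grid[(i + 1, j - 1)].upsample_bilinear2x())
                grid[(i, j)] = self.nodes[(i, j)](ins)
        head_probs = []
        for j, head in enumerate(self.heads, start=1):
            logits = head(grid[(0, j)]).upsample_bilinear2x()
            if self.cfg.head_activation == "sigmoid":
                s = logits.sigmoid()
                # renormalise across classes so the maps are probabilities
                probs = s / (s.sum(axis=1, keepdims=True) + 1e-7)
            else:
                probs = logits.softmax(axis=1)
            head_probs.append(probs)
        if self.cfg.deep_supervision_combine == "mean":
            combined = head_probs[0]
            for p in head_probs[1:]:
                combined = combined + p
            combined = combined * (1.0 / len(head_probs))
        else:
            combined = head_probs[-1]
        return {"probs": combined, "heads": head_probs}

    # -- convenience -------------------------------------------------------
    def predict(self, x) -> np.ndarray:
        """Per-pixel argmax class labels (ties resolve to the lower class)."""
        with nn.no_grad():
            out = self.forward(x)
        return np.argmax(out["probs"].data, axis=1).astype(np.uint8)

    def set_probe_identity(self, flag: bool = True):
        """Force all decoder attention gates to 1 (ablation probe)."""
        for node in self.nodes.values():
            node.att.probe_identity = flag

    # children discovery: self.nodes is a plain dict keyed by tuples, expose
    # its modules through node_list (already a ModuleList attribute)


def save_checkpoint(path, model: RsprUnetPP, extra: dict | None = None):
    state = model.state_dict()
    payload = {f"state/{k}": v for k, v in state.items()}
    np.savez_compressed(
        path,
        __config__=np.frombuffer(model.cfg.to_json().encode(), dtype=np.uint8),
        __extra__=np.frombuffer(json.dumps(extra or {}).encode(), dtype=np.uint8),
        **payload,
    )


def load_checkpoint(path, seed: int = 0):
    with np.load(path) as f:
        cfg = ModelConfig.from_json(bytes(f["__config__"]).decode())
        extra = json.loads(bytes(f["__extra__"]).decode())
        state = {k[len("state/"):]: f[k] for k in f.files if k.startswith("state/")}
    model = RsprUnetPP(cfg, seed=seed)
    model.load_state_dict(state)
    model.eval()
    return model, extra
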