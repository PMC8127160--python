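"""The segmentation network: a 4-stage 3D attention-gated U-net whose deep
stages use deformable convolutions.

Encoder stages 1-2 are regular dilated convolutions (kernel 11 dilation 3,
kernel 9 dilation 2 — large receptive fields at full resolution); stages 3-4,
the central stage and decoder stages 4-3 are deformable blocks (an
offset-predicting standard convolution, a deformable convolution sampling the
input at learned sub-voxel offsets, then another standard convolution, all of
the same kernel size and padding); decoder stages 2-1 are regular kernels 5
and 7.  Every convolution is size-preserving; resolution changes only through
the four 2x2x2 max-poolings and the four factor-2 trilinear upsamplings.
Attention gates sit on decoder levels 2-4; the central stage's output is the
gating signal for the deepest gate.  Per level the gated skip and the
upsampled decoder features are concatenated and fused by a kernel-1
convolution; a final kernel-1 convolution maps to the three class scores.

Channel widths are not part of the published layer table; the default is 16
at the first level, doubling per level, and is configurable (`base_channels`).
Offset predictors are zero-initialized so training starts from the
regular-convolution regime.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = ["StageSpec", "NetworkConfig", "GPNet", "build_network", "forward",
           "deformable_conv3d", "attention_gate", "save_checkpoint",
           "load_checkpoint", "DEFAULT_STAGE_SPECS"]


@dataclass(frozen=True)
class StageSpec:
    level: int
    path: str            # "encoder" | "central" | "decoder" | "final"
    layer_type: str      # "regular" | "deformable"
    kernel_size: int
    padding: int
    dilation: int = 1


DEFAULT_STAGE_SPECS: tuple[StageSpec, ...] = (
    StageSpec(1, "encoder", "regular", 11, 15, 3),
    StageSpec(2, "encoder", "regular", 9, 8, 2),
    StageSpec(3, "encoder", "deformable", 5, 2, 1),
    StageSpec(4, "encoder", "deformable", 3, 1, 1),
    StageSpec(5, "central", "deformable", 3, 1, 1),
    StageSpec(4, "decoder", "deformable", 3, 1, 1),
    StageSpec(3, "decoder", "deformable", 3, 1, 1),
    StageSpec(2, "decoder", "regular", 5, 2, 1),
    StageSpec(1, "decoder", "regular", 7, 3, 1),
    StageSpec(0, "final", "regular", 1, 0, 1),
)


class ConfigError(ValueError):
    pass


@dataclass
class NetworkConfig:
    num_stages: int = 4
    stage_specs: tuple[StageSpec, ...] = DEFAULT_STAGE_SPECS
    base_channels: int = 16
    channel_multiplier: int = 2
    num_classes: int = 3
    attention_gate_levels: tuple[int, ...] = (2, 3, 4)
    init_gain: float = 0.05
    dtype: str = "float32"

    def __post_init__(self):
        self.stage_specs = tuple(
            s if isinstance(s, StageSpec) else StageSpec(**s)
            for s in self.stage_specs)
        for s in self.stage_specs:
            if s.layer_type == "regular":
                if 2 * s.padding != s.dilation * (s.kernel_size - 1):
                    raise ConfigError(
                        f"regular conv at {s.path} level {s.level} is not "
                        f"size-preserving: padding {s.padding}, kernel "
                        f"{s.kernel_size}, dilation {s.dilation}")
            elif s.layer_type == "deformable":
                if s.dilation != 1:
                    raise ConfigError("deformable convolutions carry no dilation")
                if 2 * s.padding != s.kernel_size - 1:
                    raise ConfigError(
                        f"deformable conv at {s.path} level {s.level} is not "
                        "size-preserving")
            else:
                raise ConfigError(f"unknown layer type {s.layer_type!r}")
        if self.num_stages < 1 or self.base_channels < 1:
            raise ConfigError("num_stages and base_channels must be >= 1")

    def stage(self, path: str, level: int) -> StageSpec:
        for s in self.stage_specs:
            if s.path == path and s.level == level:
                return s
        raise ConfigError(f"no stage spec for {path} level {level}")

    def channels(self, level: int) -> int:
        return self.base_channels * self.channel_multiplier ** (level - 1)

    def to_json(self) -> str:
        d = asdict(self)
        d["stage_specs"] = [asdict(s) for s in self.stage_specs]
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "NetworkConfig":
        d = json.loads(text)
        d["stage_specs"] = tuple(StageSpec(**s) for s in d["stage_specs"])
        d["attention_gate_levels"] = tuple(d["attention_gate_levels"])
        return cls(**d)


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class Module:
    """Tiny parameter container; submodules discovered from attributes."""

    def named_parameters(self, prefix=""):
        out = {}
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                out[key] = value
            elif isinstance(value, Module):
                out.update(value.named_parameters(f"{key}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.update(item.named_parameters(f"{key}.{i}."))
        return out

    def named_buffers(self, prefix=""):
        out = {}
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, np.ndarray):
                out[key] = value
            elif isinstance(value, Module):
                out.update(value.named_buffers(f"{key}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.update(item.named_buffers(f"{key}.{i}."))
        return out

    def parameters(self):
        return list(self.named_parameters().values())


class Conv3d(Module):
    def __init__(self, cin, cout, kernel_size, padding=0, dilation=1,
                 rng=None, zero_init=False, bias=True, dtype=np.float32,
                 gain=1.0):
        k = kernel_size
        if zero_init:
            w = np.zeros((cout, cin, k, k, k), dtype=dtype)
        else:
            std = gain * np.sqrt(2.0 / (cin * k ** 3))
            w = (rng.standard_normal((cout, cin, k, k, k)) * std).astype(dtype)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(cout, dtype=dtype), requires_grad=True) if bias else None
        self.padding = padding
        self.dilation = dilation

    def __call__(self, x, training=False):
        return ag.conv3d(x, self.weight, self.bias,
                         padding=self.padding, dilation=self.dilation)


class BatchNorm3d(Module):
    def __init__(self, channels, dtype=np.float32):
        self.gamma = Tensor(np.ones(channels, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)

    def __call__(self, x, training=False):
        return ag.batchnorm(x, self.gamma, self.beta, self.running_mean,
                            self.running_var, training=training)


class ConvBNReLU(Module):
    def __init__(self, cin, cout, kernel_size, padding, dilation, rng,
                 dtype=np.float32, gain=1.0):
        self.conv = Conv3d(cin, cout, kernel_size, padding, dilation,
                           rng=rng, dtype=dtype, gain=gain)
        self.bn = BatchNorm3d(cout, dtype=dtype)

    def __call__(self, x, training=False):
        return self.bn(self.conv(x), training=training).relu()


def deformable_conv3d(features, offsets, weight, bias=None, padding=None):
    """Deformable convolution: sample at regular taps plus predicted offsets.

    ``offsets`` must carry 3*k^3 channels for kernel size k (z, y, x
    displacement per tap); sampling is trilinear with zero outside the grid.
    With all offsets zero this is exactly a standard convolution.
    """
    return ag.deformable_conv3d_op(features, offsets, weight, b=bias,
                                   padding=padding)


class DeformableBlock(Module):
    """Offset conv -> deformable conv -> standard conv, BN+ReLU after each
    feature-producing convolution; all convolutions share kernel and padding."""

    def __init__(self, cin, cout, kernel_size, padding, rng, dtype=np.float32,
                 gain=1.0):
        k = kernel_size
        self.offset_conv = Conv3d(cin, 3 * k ** 3, k, padding, 1,
                                  rng=rng, zero_init=True, dtype=dtype)
        std = gain * np.sqrt(2.0 / (cin * k ** 3))
        self.weight = Tensor(
            (rng.standard_normal((cout, cin, k, k, k)) * std).astype(dtype),
            requires_grad=True)
        self.bias = Tensor(np.zeros(cout, dtype=dtype), requires_grad=True)
        self.bn1 = BatchNorm3d(cout, dtype=dtype)
        self.post_conv = Conv3d(cout, cout, k, padding, 1, rng=rng, dtype=dtype,
                                gain=gain)
        self.bn2 = BatchNorm3d(cout, dtype=dtype)
        self.padding = padding

    def __call__(self, x, training=False):
        offsets = self.offset_conv(x)
        y = deformable_conv3d(x, offsets, self.weight, self.bias, self.padding)
        y = self.bn1(y, training=training).relu()
        y = self.bn2(self.post_conv(y), training=training).relu()
        return y


class AttentionGate(Module):
    """Additive attention: kernel-1 projections of skip and gating signals are
    summed (at the gating resolution), passed through ReLU, projected to one
    channel, squashed by a sigmoid and upsampled to scale the skip features."""

    def __init__(self, skip_channels, gating_channels, rng, dtype=np.float32):
        inter = max(skip_channels // 2, 1)
        self.theta = Conv3d(skip_channels, inter, 1, rng=rng, bias=False, dtype=dtype)
        self.phi = Conv3d(gating_channels, inter, 1, rng=rng, dtype=dtype)
        self.psi = Conv3d(inter, 1, 1, rng=rng, dtype=dtype)

    def __call__(self, skip, gating, training=False):
        s_shape = skip.data.shape[1:]
        g_shape = gating.data.shape[1:]
        tx = self.theta(skip)
        if tuple(g_shape) == tuple(n // 2 for n in s_shape):
            tx = ag.avgpool2(tx)
            upsample = True
        elif tuple(g_shape) == tuple(s_shape):
            upsample = False
        else:
            raise ConfigError(
                f"gating resolution {g_shape} incompatible with skip {s_shape}")
        a = (tx + self.phi(gating)).relu()
        coef = self.psi(a).sigmoid()
        if upsample:
            coef = ag.upsample2(coef)
        return skip * coef


def attention_gate(skip, gating, gate: AttentionGate):
    """Apply an attention gate module to (skip, gating) feature maps."""
    return gate(skip, gating)


# ---------------------------------------------------------------------------
# The full network
# ---------------------------------------------------------------------------

class GPNet(Module):
    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        self.cfg = cfg
        dtype = np.dtype(cfg.dtype).type
        rng = np.random.default_rng(seed)
        m = cfg.num_stages
        ch = [None] + [cfg.channels(l) for l in range(1, m + 1)]
        central_ch = cfg.channels(m + 1)

        self.encoder = []
        cin = 1
        for l in range(1, m + 1):
            s = cfg.stage("encoder", l)
            if s.layer_type == "regular":
                stage = _RegularStage(cin, ch[l], s, rng, dtype, gain=cfg.init_gain)
            else:
                stage = DeformableBlock(cin, ch[l], s.kernel_size, s.padding,
                                        rng, dtype, gain=cfg.init_gain)
            self.encoder.append(stage)
            cin = ch[l]
        cs = cfg.stage("central", m + 1)
        self.central = DeformableBlock(ch[m], central_ch, cs.kernel_size,
                                       cs.padding, rng, dtype,
                                       gain=cfg.init_gain)

        self.decoder = []
        self.gates = []
        self.merge = []
        prev_ch = central_ch
        gate_gating_ch = {4: central_ch}
        for l in range(m, 0, -1):
            s = cfg.stage("decoder", l)
            if s.layer_type == "regular":
                block = ConvBNReLU(prev_ch, ch[l], s.kernel_size, s.padding,
                                   s.dilation, rng, dtype, gain=cfg.init_gain)
            else:
                block = DeformableBlock(prev_ch, ch[l], s.kernel_size,
                                        s.padding, rng, dtype,
                                        gain=cfg.init_gain)
            self.decoder.append(block)
            if l in cfg.attention_gate_levels:
                self.gates.append(AttentionGate(ch[l],
                                                gate_gating_ch.get(l, prev_ch),
                                                rng, dtype))
            else:
                self.gates.append(None)
            self.merge.append(Conv3d(2 * ch[l], ch[l], 1, rng=rng, dtype=dtype))
            prev_ch = ch[l]
        fs = cfg.stage("final", 0)
        self.final = Conv3d(prev_ch, cfg.num_classes, fs.kernel_size,
                            fs.padding, fs.dilation, rng=rng, dtype=dtype)
        self.dtype = dtype

    # -- forward ------------------------------------------------------------

    def __call__(self, image, training=False):
        x = self._prepare_input(image)
        m = self.cfg.num_stages
        skips = []
        for stage in self.encoder:
            x = stage(x, training=training)
            skips.append(x)
            x = ag.maxpool2(x)
        x = self.central(x, training=training)
        gating = x
        for i, l in enumerate(range(m, 0, -1)):
            x = self.decoder[i](x, training=training)
            x = ag.upsample2(x)
            skip = skips[l - 1]
            if self.gates[i] is not None:
                skip = self.gates[i](skip, gating, training=training)
            x = self.merge[i](ag.concat([skip, x], axis=0))
            gating = x
        return self.final(x)

    def _prepare_input(self, image):
        if isinstance(image, Tensor):
            x = image
            data = x.data
        else:
            data = np.asarray(image)
            x = None
        data = np.squeeze(data) if data.ndim > 3 else data
        if data.ndim != 3:
            raise ValueError(f"expected a 3D input volume, got shape {data.shape}")
        div = 2 ** self.cfg.num_stages
        for ax, n in enumerate(data.shape):
            if n % div:
                raise ValueError(
                    f"input axis {ax} has length {n}, not divisible by {div}")
        if x is None or x.data.ndim != 4:
            x = Tensor(data[None].astype(self.dtype),
                       requires_grad=x.requires_grad if x else False)
        return x


class _RegularStage(Module):
    """Two consecutive convolution/BN/ReLU blocks with identical parameters."""

    def __init__(self, cin, cout, spec: StageSpec, rng, dtype, gain=1.0):
        self.block1 = ConvBNReLU(cin, cout, spec.kernel_size, spec.padding,
                                 spec.dilation, rng, dtype, gain=gain)
        self.block2 = ConvBNReLU(cout, cout, spec.kernel_size, spec.padding,
                                 spec.dilation, rng, dtype, gain=gain)

    def __call__(self, x, training=False):
        return self.block2(self.block1(x, training=training), training=training)


def build_network(cfg: NetworkConfig | None = None, seed: int = 0) -> GPNet:
    """Construct the network with deterministic, seeded initialization."""
    return GPNet(cfg or NetworkConfig(), seed=seed)


def forward(net: GPNet, image) -> np.ndarray:
    """Evaluation-mode forward pass; returns class scores (num_classes, D, H, W)."""
    return net(image, training=False).data


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(net: GPNet, path, extra: dict | None = None) -> None:
    """Serialize weights, BN statistics and the embedded config to one file."""
    arrays = {f"param/{k}": v.data for k, v in net.named_parameters().items()}
    arrays.update({f"buffer/{k}": v for k, v in net.named_buffers().items()})
    meta = {"config": net.cfg.to_json(), "extra": extra or {}}
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(str(path), **arrays)


def load_checkpoint(path) -> tuple[GPNet, dict]:
    """Rebuild a network from a checkpoint; returns (net, extra_metadata)."""
    with np.load(str(path)) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        cfg = NetworkConfig.from_json(meta["config"])
        net = GPNet(cfg, seed=0)
        params = net.named_parameters()
        buffers = net.named_buffers()
        for key in data.files:
            if key.startswith("param/"):
                params[key[6:]].data = data[key].astype(net.dtype)
            elif key.startswith("buffer/"):
                buffers[key[7:]][...] = data[key]
    return net, meta["extra"]
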