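"""Network building blocks: (2+1)D convolution, residual blocks, 3D
squeeze-and-excitation attention, and the full classification model.

The model is a stack of five residual-with-parallel-attention (RPA) stages
interleaved with four downsampling stages, followed by global average
pooling and a dense head that emits raw two-class logits. Each RPA stage is
a residual block whose output passes through P-scSE3D: the parallel
combination of channel excitation (cSE3D) and spatial excitation (sSE3D)
via a max-out branch plus an additive branch. At low channel counts the
max-out branch is bypassed ("shorted" form).

Full 3D convolutions are replaced throughout by the (2+1)D factorization —
a 1xkxk spatial convolution into M intermediate channels followed by a
tx1x1 temporal convolution — which cuts the parameter count from
``t*k^2*C_in*C_out`` to ``k^2*C_in*M + t*M*C_out``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .nn import ConfigurationError, Module

__all__ = [
    "BlockConfig",
    "ArchitectureConfig",
    "Conv2Plus1D",
    "ResidualBlock",
    "CSE3D",
    "SSE3D",
    "PScSE3D",
    "RPABlock",
    "Downsample",
    "Model",
    "build_model",
    "mid_channels_rule",
    "conv2plus1d_param_count",
    "full3d_param_count",
]


def mid_channels_rule(c_in: int, c_out: int, k: int, t: int) -> int:
    """Parameter-matching intermediate width M for the (2+1)D factorization.

    ``M = floor(t*k^2*C_in*C_out / (k^2*C_in + t*C_out))`` keeps the
    factorized layer's budget close to the full 3D convolution it replaces;
    when the division is exact the floor alone only matches the full budget,
    so M is decremented until the factorization is strictly cheaper
    (clamped to at least 1).
    """
    m = max(1, (t * k * k * c_in * c_out) // (k * k * c_in + t * c_out))
    full = full3d_param_count(c_in, c_out, k, t)
    while m > 1 and conv2plus1d_param_count(c_in, c_out, k, t, m) >= full:
        m -= 1
    return m


def conv2plus1d_param_count(c_in: int, c_out: int, k: int, t: int, m: int) -> int:
    """Weight count (ignoring biases) of the factorized convolution."""
    return k * k * c_in * m + t * m * c_out


def full3d_param_count(c_in: int, c_out: int, k: int, t: int) -> int:
    """Weight count (ignoring biases) of the equivalent full 3D convolution."""
    return t * k * k * c_in * c_out


@dataclass
class BlockConfig:
    """Per-stage hyperparameters.

    Parameters
    ----------
    out_channels : output width of the stage.
    spatial_kernel, temporal_kernel : odd kernel sizes k and t.
    mid_channels : intermediate width M of the (2+1)D factorization;
        ``None`` applies :func:`mid_channels_rule`.
    reduction_ratio : bottleneck ratio r of the channel-excitation block.
    sw_bypass_threshold : channel count below which the max-out branch of
        P-scSE3D is bypassed (the "shorted" switch).
    """

    out_channels: int
    spatial_kernel: int = 3
    temporal_kernel: int = 3
    mid_channels: int | None = None
    reduction_ratio: int = 2
    sw_bypass_threshold: int = 32

    def __post_init__(self):
        if self.out_channels < 1:
            raise ConfigurationError("out_channels must be positive")
        for name in ("spatial_kernel", "temporal_kernel"):
            v = getattr(self, name)
            if v < 1 or v % 2 == 0:
                raise ConfigurationError(f"{name} must be odd and positive, got {v}")
        if self.reduction_ratio < 1 or self.sw_bypass_threshold < 1:
            raise ConfigurationError("reduction_ratio and sw_bypass_threshold must be positive")
        if self.out_channels // self.reduction_ratio < 1:
            raise ConfigurationError(
                f"reduction ratio {self.reduction_ratio} leaves no bottleneck units "
                f"for {self.out_channels} channels"
            )


@dataclass
class ArchitectureConfig:
    """Whole-network description: five RPA stages, four downsample stages.

    ``use_attention=False`` replaces every RPA block by its residual block
    alone (the ablation arm), leaving depth and width unchanged.
    """

    stage_widths: tuple[int, ...] = (16, 32, 64, 128, 256)
    in_channels: int = 3
    n_classes: int = 2
    spatial_kernel: int = 3
    temporal_kernel: int = 3
    reduction_ratio: int = 2
    sw_bypass_threshold: int = 32
    use_attention: bool = True
    stage_overrides: dict = field(default_factory=dict)

    n_rpa: int = 5
    n_downsample: int = 4

    def __post_init__(self):
        self.stage_widths = tuple(self.stage_widths)
        if len(self.stage_widths) != self.n_rpa:
            raise ConfigurationError(
                f"expected {self.n_rpa} stage widths, got {len(self.stage_widths)}"
            )
        if self.n_rpa != 5 or self.n_downsample != 4:
            raise ConfigurationError("the architecture has 5 RPA and 4 downsample stages")

    def block_config(self, stage: int) -> BlockConfig:
        kwargs = dict(
            out_channels=self.stage_widths[stage],
            spatial_kernel=self.spatial_kernel,
            temporal_kernel=self.temporal_kernel,
            reduction_ratio=self.reduction_ratio,
            sw_bypass_threshold=self.sw_bypass_threshold,
        )
        kwargs.update(self.stage_overrides.get(stage, {}))
        return BlockConfig(**kwargs)

    def to_json(self) -> str:
        d = asdict(self)
        d["stage_overrides"] = {str(k): v for k, v in self.stage_overrides.items()}
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ArchitectureConfig":
        d = json.loads(text)
        d["stage_overrides"] = {int(k): v for k, v in d.get("stage_overrides", {}).items()}
        d["stage_widths"] = tuple(d["stage_widths"])
        return cls(**d)


class Conv2Plus1D(Module):
    """(2+1)D convolution: spatial 1xkxk to M channels, temporal tx1x1 to C_out."""

    def __init__(self, c_in: int, cfg: BlockConfig, rng: np.random.Generator,
                 c_out: int | None = None):
        c_out = cfg.out_channels if c_out is None else c_out
        k, t = cfg.spatial_kernel, cfg.temporal_kernel
        m = cfg.mid_channels or mid_channels_rule(c_in, c_out, k, t)
        self.c_in, self.c_out, self.mid_channels = c_in, c_out, m
        self.spatial = nn.SpatialConv(c_in, m, k, rng)
        self.temporal = nn.TemporalConv(m, c_out, t, rng)

    def forward(self, x):
        return self.temporal(self.spatial(x))

    def backward(self, g):
        return self.spatial.backward(self.temporal.backward(g))


class ResidualBlock(Module):
    """conv -> layer norm -> ReLU -> conv -> layer norm, plus a skip.

    The skip is the identity when channel counts match and a 1x1x1
    projection otherwise. No activation follows the addition. When asked,
    the block records the output of (and the loss gradient at) its second
    convolution, which serves as the "last convolutional layer" hook for
    Grad-CAM.
    """

    def __init__(self, c_in: int, cfg: BlockConfig, rng: np.random.Generator):
        c_out = cfg.out_channels
        self.conv1 = Conv2Plus1D(c_in, cfg, rng)
        self.ln1 = nn.LayerNorm(c_out)
        self.relu = nn.ReLU()
        self.conv2 = Conv2Plus1D(c_out, cfg, rng)
        self.ln2 = nn.LayerNorm(c_out)
        self.proj = nn.PointwiseConv(c_in, c_out, rng) if c_in != c_out else None
        self.record_conv2 = False
        self.conv2_out: np.ndarray | None = None
        self.conv2_grad: np.ndarray | None = None

    def forward(self, x):
        h = self.relu(self.ln1(self.conv1(x)))
        h = self.conv2(h)
        if self.record_conv2:
            self.conv2_out = h
        h = self.ln2(h)
        skip = x if self.proj is None else self.proj(x)
        return h + skip

    def backward(self, g):
        g_skip = g if self.proj is None else self.proj.backward(g)
        gh = self.ln2.backward(g)
        if self.record_conv2:
            self.conv2_grad = gh
        gh = self.conv1.backward(self.ln1.backward(self.relu.backward(self.conv2.backward(gh))))
        return gh + g_skip


class CSE3D(Module):
    """Spatial squeeze + channel excitation.

    Global average pooling over (T,H,W) feeds a two-layer bottleneck
    (C -> C/r -> C) whose sigmoid output gates each channel of the input.
    """

    def __init__(self, c: int, r: int, rng: np.random.Generator):
        if c < r:
            raise ConfigurationError(f"need at least r={r} channels for the cSE bottleneck, got {c}")
        self.fc1 = nn.Dense(c, c // r, rng)
        self.act = nn.ReLU()
        self.fc2 = nn.Dense(c // r, c, rng)
        self.sig = nn.Sigmoid()

    def forward(self, x):
        self._x = x
        z = x.mean(axis=(1, 2, 3))  # B,C
        self._gate = self.sig(self.fc2(self.act(self.fc1(z))))
        return x * self._gate[:, None, None, None, :]

    def backward(self, g):
        x, gate = self._x, self._gate
        gx = g * gate[:, None, None, None, :]
        g_gate = (g * x).sum(axis=(1, 2, 3))
        gz = self.fc1.backward(self.act.backward(self.fc2.backward(self.sig.backward(g_gate))))
        _, T, H, W, _ = x.shape
        return gx + gz[:, None, None, None, :] / float(T * H * W)


class SSE3D(Module):
    """Channel squeeze + spatial excitation: a 1x1x1 convolution to one
    channel, passed through a sigmoid, gates every spatiotemporal position."""

    def __init__(self, c: int, rng: np.random.Generator):
        self.squeeze = nn.PointwiseConv(c, 1, rng)
        self.sig = nn.Sigmoid()

    def forward(self, x):
        self._x = x
        self._gate = self.sig(self.squeeze(x))  # B,T,H,W,1
        return x * self._gate

    def backward(self, g):
        gx = g * self._gate
        g_gate = (g * self._x).sum(axis=-1, keepdims=True)
        return gx + self.squeeze.backward(self.sig.backward(g_gate))


class PScSE3D(Module):
    """Parallel spatial/channel squeeze-and-excitation.

    With ``c = cSE(x)`` and ``s = sSE(x)`` the full form returns
    ``max(c, s) + (c + s)``; when the input has fewer channels than
    ``sw_bypass_threshold`` the max-out branch is bypassed ("shorted")
    and the output is ``c + s``.
    """

    def __init__(self, c: int, cfg: BlockConfig, rng: np.random.Generator):
        self.cse = CSE3D(c, cfg.reduction_ratio, rng)
        self.sse = SSE3D(c, rng)
        self.shorted = c < cfg.sw_bypass_threshold

    def forward(self, x):
        c = self.cse(x)
        s = self.sse(x)
        if self.shorted:
            return c + s
        self._mask = c >= s  # ties route the max-out gradient to the cSE branch
        return np.maximum(c, s) + c + s

    def backward(self, g):
        if self.shorted:
            gc = gs = g
        else:
            gc = g * (1.0 + self._mask)
            gs = g * (1.0 + ~self._mask)
        return self.cse.backward(gc) + self.sse.backward(gs)


class RPABlock(Module):
    """Residual block followed by P-scSE3D (or the residual block alone
    when attention is disabled for the ablation arm)."""

    def __init__(self, c_in: int, cfg: BlockConfig, rng: np.random.Generator,
                 use_attention: bool = True):
        self.residual = ResidualBlock(c_in, cfg, rng)
        self.attention = PScSE3D(cfg.out_channels, cfg, rng) if use_attention else None

    def forward(self, x):
        h = self.residual(x)
        return h if self.attention is None else self.attention(h)

    def backward(self, g):
        if self.attention is not None:
            g = self.attention.backward(g)
        return self.residual.backward(g)


class Downsample(Module):
    """Halves the spatial extents (and the temporal extent while it is >= 2)
    by stride-2 max pooling; channels are unchanged."""

    def __init__(self):
        self.pool = nn.MaxPool3D(pool_time=True)

    def forward(self, x):
        return self.pool(x)

    def backward(self, g):
        return self.pool.backward(g)


class Model(Module):
    """Five RPA stages, four downsample stages, and a pooled dense head.

    ``forward`` returns raw logits of shape (batch, n_classes); the softmax
    lives in the loss and in prediction-time probability conversion.
    ``backward`` propagates a logit gradient all the way to the input, which
    is what guided backpropagation consumes.
    """

    def __init__(self, arch: ArchitectureConfig, seed: int | np.random.SeedSequence = 0):
        rng = np.random.default_rng(seed)
        self.arch = arch
        stages: list[Module] = []
        c_in = arch.in_channels
        for i in range(arch.n_rpa):
            cfg = arch.block_config(i)
            stages.append(RPABlock(c_in, cfg, rng, use_attention=arch.use_attention))
            c_in = cfg.out_channels
            if i < arch.n_downsample:
                stages.append(Downsample())
        self.body = nn.Sequential(*stages)
        self.gap = nn.GlobalAvgPool()
        self.head = nn.Dense(c_in, arch.n_classes, rng)
        self.rpa_blocks = [s for s in stages if isinstance(s, RPABlock)]

    def forward(self, x, capture_cam: bool = False):
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 5:
            raise ConfigurationError(f"expected a (B,T,H,W,C) volume, got shape {x.shape}")
        min_hw = 2 ** self.arch.n_downsample
        if x.shape[2] < min_hw or x.shape[3] < min_hw:
            raise ConfigurationError(
                f"input {x.shape[2]}x{x.shape[3]} too small for "
                f"{self.arch.n_downsample} halvings (needs >= {min_hw})"
            )
        self.rpa_blocks[-1].residual.record_conv2 = capture_cam
        h = self.body(x)
        return self.head(self.gap(h))

    def backward(self, dlogits):
        return self.body.backward(self.gap.backward(self.head.backward(dlogits)))

    @property
    def cam_activation(self) -> np.ndarray | None:
        """Last forward pass's final-stage conv output (if captured)."""
        return self.rpa_blocks[-1].residual.conv2_out

    @property
    def cam_gradient(self) -> np.ndarray | None:
        return self.rpa_blocks[-1].residual.conv2_grad

    def save(self, path):
        """Write weights (NPZ) next to a JSON architecture description."""
        arrays = {name: p.value for name, p in self.named_params()}
        np.savez(path, **arrays)
        cfg_path = str(path)
        cfg_path = cfg_path[: -len(".npz")] if cfg_path.endswith(".npz") else cfg_path
        with open(cfg_path + ".json", "w") as fh:
            fh.write(self.arch.to_json())

    @classmethod
    def load(cls, path) -> "Model":
        cfg_path = str(path)
        cfg_path = cfg_path[: -len(".npz")] if cfg_path.endswith(".npz") else cfg_path
        with open(cfg_path + ".json") as fh:
            arch = ArchitectureConfig.from_json(fh.read())
        model = cls(arch, seed=0)
        with np.load(path) as data:
            for name, p in model.named_params():
                p.value[...] = data[name]
        return model


def build_model(arch: ArchitectureConfig, seed: int | np.random.SeedSequence = 0) -> Model:
    """Construct the full network with seeded variance-scaling init."""
    return Model(arch, seed=seed)
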