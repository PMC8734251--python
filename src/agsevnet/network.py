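"""The AGSE-VNet: a V-Net-shaped 3D encoder/decoder with
squeeze-and-excitation channel recalibration in every encoder stage and
attention-guided-filter skip connections in every decoder stage.

Encoder stage: 2-3 convolutions (3x3x3, instance norm, ReLU, dropout)
with a residual addition of the stage input, an SE block, then a
stride-2 3x3x3 convolution that halves each spatial dimension and
doubles the channel count. The decoder mirrors it: a stride-2
transposed convolution restores resolution and halves channels, the AG
module filters the pre-upsampling decoder feature with a guidance map
derived from the matching encoder feature, and convolutions with a
residual addition fuse the two paths. A final 1x1x1 convolution to 4
channels plus a voxelwise softmax produces class probabilities.

Design notes: normalization is instance norm (well behaved at batch
size 1 for 3D patches); the softmax head is consistent with one-hot
targets and the Dice objective; residual shortcuts use a 1x1x1
projection when channel counts differ. Setting ``use_se=False`` and/or
``use_agf=False`` in the config degrades the model to a plain V-Net
baseline with concatenation skips and an identical I/O contract,
which is what the ablation tests exercise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .blocks import guided_filter_coeffs_core

__all__ = [
    "NetworkConfig",
    "conv_output_size",
    "deconv_output_size",
    "AGSEVNet",
    "build_network",
    "save_checkpoint",
    "load_checkpoint",
]


# ---------------------------------------------------------------------
# convolution size arithmetic
# ---------------------------------------------------------------------

def conv_output_size(i: int, k: int, s: int, p: int) -> int:
    """o = floor((i + 2p - k)/s) + 1 for a strided convolution."""
    if k > i + 2 * p:
        raise ValueError(f"kernel {k} exceeds padded input {i + 2 * p}")
    if min(i, k, s) < 1 or p < 0:
        raise ValueError("sizes must be positive, padding non-negative")
    return (i + 2 * p - k) // s + 1


def deconv_output_size(i: int, k: int, s: int, p: int,
                       target: int | None = None) -> tuple[int, int]:
    """Transposed-convolution output size with output_padding.

    o = s(i-1) + k - 2p + output_padding, with output_padding in {0, 1}
    chosen so that o equals ``target`` (default s*i, i.e. a stride-2
    deconvolution exactly doubles). Returns (o, output_padding); raises
    when no output_padding in {0, 1} reaches the target.
    """
    if min(i, k, s) < 1 or p < 0:
        raise ValueError("sizes must be positive, padding non-negative")
    target = s * i if target is None else target
    base = s * (i - 1) + k - 2 * p
    for op in (0, 1):
        if base + op == target:
            return target, op
    raise ValueError(
        f"no output_padding in {{0,1}} reaches {target} from o0={base}"
    )


# ---------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------

@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    patch_shape must be divisible by 2**n_encoder_stages; base_channels
    is the width of stage 1 (doubled at each downsampling) and must be
    divisible by se_reduction.
    """

    n_encoder_stages: int = 4
    convs_per_block: int = 2
    base_channels: int = 16
    dropout_rate: float = 0.5
    n_classes: int = 4
    input_channels: int = 4
    patch_shape: tuple[int, int, int] = (64, 128, 128)
    se_reduction: int = 4
    agf_radius: int = 16
    agf_epsilon: float = 0.01
    use_se: bool = True
    use_agf: bool = True

    def __post_init__(self):
        if self.n_classes != 4:
            raise ValueError("the label convention fixes n_classes = 4")
        if not 2 <= self.convs_per_block <= 3:
            raise ValueError("convs_per_block must be 2 or 3")
        f = 2 ** self.n_encoder_stages
        if any(n % f for n in self.patch_shape):
            raise ValueError(
                f"patch_shape {self.patch_shape} not divisible by {f}"
            )
        if self.base_channels % self.se_reduction:
            raise ValueError("base_channels must be divisible by se_reduction")


# ---------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------

class Module:
    """Tiny parameter-container base class."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params


def _he_init(rng, shape, fan_in) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Conv3d(Module):
    def __init__(self, c_in, c_out, k=3, stride=1, padding=None, rng=None):
        rng = rng or np.random.default_rng(0)
        padding = (k - 1) // 2 if padding is None else padding
        self.stride, self.padding = stride, padding
        self.weight = Tensor(
            _he_init(rng, (k, k, k, c_in, c_out), k**3 * c_in), requires_grad=True)
        self.bias = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv3d(x, self.weight, self.bias,
                         stride=self.stride, padding=self.padding)


class ConvTranspose3d(Module):
    """Stride-2 transposed convolution with a 2x2x2 kernel: exact doubling."""

    def __init__(self, c_in, c_out, k=2, stride=2, rng=None):
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.weight = Tensor(
            _he_init(rng, (k, k, k, c_in, c_out), k**3 * c_in), requires_grad=True)
        self.bias = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv_transpose3d(x, self.weight, self.bias,
                                   stride=self.stride, padding=0,
                                   output_padding=0)


class InstanceNorm(Module):
    """Per-sample, per-channel normalization over the spatial axes."""

    def __init__(self, channels, eps=1e-5):
        self.eps = eps
        self.gamma = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        mu = ag.tmean(x, axis=(1, 2, 3), keepdims=True)
        xc = x - mu
        var = ag.tmean(xc * xc, axis=(1, 2, 3), keepdims=True)
        return xc / ((var + self.eps) ** 0.5) * self.gamma + self.beta


class SELayer(Module):
    """Squeeze-and-excitation: global average pool, two-layer gate,
    channelwise rescale. Same math as blocks.se_block."""

    def __init__(self, channels, m=4, rng=None):
        if channels % m:
            raise ValueError(f"channels {channels} not divisible by m={m}")
        rng = rng or np.random.default_rng(0)
        self.channels = channels
        self.W1 = Tensor(_he_init(rng, (channels // m, channels), channels),
                         requires_grad=True)
        self.W2 = Tensor(_he_init(rng, (channels, channels // m), channels // m),
                         requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        z = ag.tmean(x, axis=(1, 2, 3))                     # (N, C)
        h = ag.relu(ag.matmul(z, _t(self.W1)))
        s = ag.sigmoid(ag.matmul(h, _t(self.W2)))
        n, c = s.shape
        return x * ag.reshape(s, (n, 1, 1, 1, c))


def _t(w: Tensor) -> Tensor:
    """Transpose view of a weight matrix that shares its gradient."""
    out = Tensor(w.data.T, parents=(w,))
    out._backward = lambda g: w.accumulate(g.T)
    return out


class AttentionLayer(Module):
    """1x1x1-conv attention block producing a single-channel map in (0,1)."""

    def __init__(self, c_o, c_i, c_mid=None, rng=None):
        rng = rng or np.random.default_rng(0)
        c_mid = c_mid or c_o
        self.wo = Tensor(_he_init(rng, (c_o, c_mid), c_o), requires_grad=True)
        self.wi = Tensor(_he_init(rng, (c_i, c_mid), c_i), requires_grad=True)
        self.bo = Tensor(np.zeros(c_mid, dtype=np.float32), requires_grad=True)
        self.bi = Tensor(np.zeros(c_mid, dtype=np.float32), requires_grad=True)
        self.wt = Tensor(_he_init(rng, (c_mid, 1), c_mid), requires_grad=True)
        self.bt = Tensor(np.zeros(1, dtype=np.float32), requires_grad=True)

    def __call__(self, o: Tensor, i_l: Tensor) -> Tensor:
        h = ag.relu((o @ self.wo + self.bo) + (i_l @ self.wi + self.bi))
        return ag.sigmoid(h @ self.wt + self.bt)


class AGFLayer(Module):
    """Attention-guided-filter skip fusion.

    Projects the encoder skip feature to a single-channel guidance map,
    builds the attention map from the low-resolution decoder feature and
    downsampled guidance, solves the windowed ridge regression for the
    filter coefficients, upsamples them trilinearly, and applies
    O~ = A_h * I + B_h. A small floor on the attention-weight window sum
    keeps the division stable under saturated attention maps.
    """

    def __init__(self, c_skip, c_o, radius=16, epsilon=0.01, rng=None,
                 stabilizer=1e-6):
        rng = rng or np.random.default_rng(0)
        self.radius, self.epsilon, self.stabilizer = radius, epsilon, stabilizer
        self.proj = Conv3d(c_skip, 1, k=1, rng=rng)
        self.attention = AttentionLayer(c_o, 1, rng=rng)
        self._counts: dict[tuple, np.ndarray] = {}

    def _n(self, spatial) -> np.ndarray:
        key = tuple(spatial)
        if key not in self._counts:
            ones = np.ones(key, dtype=np.float32)
            from .autograd import boxsum3d_np
            self._counts[key] = boxsum3d_np(ones, self.radius)[None, ..., None]
        return self._counts[key]

    def __call__(self, skip: Tensor, o_low: Tensor) -> Tensor:
        guidance = self.proj(skip)                       # (N, D, H, W, 1)
        factor = skip.shape[1] // o_low.shape[1]
        i_l = ag.avg_pool3d(guidance, factor) if factor > 1 else guidance
        t = self.attention(o_low, i_l)
        n = self._n(o_low.shape[1:4])
        a_l, b_l = guided_filter_coeffs_core(
            i_l, o_low, t, self.radius, self.epsilon,
            boxsum=lambda x: ag.boxsum3d(x, self.radius), n=n,
            stabilizer=self.stabilizer,
        )
        a_h = ag.upsample_trilinear3d(a_l, factor) if factor > 1 else a_l
        b_h = ag.upsample_trilinear3d(b_l, factor) if factor > 1 else b_l
        return a_h * guidance + b_h


class ConvBlock(Module):
    """conv -> instance norm -> ReLU -> dropout."""

    def __init__(self, c_in, c_out, dropout, rng):
        self.conv = Conv3d(c_in, c_out, k=3, rng=rng)
        self.norm = InstanceNorm(c_out)
        self.dropout = dropout

    def __call__(self, x, rng, training):
        h = ag.relu(self.norm(self.conv(x)))
        return ag.dropout(h, self.dropout, rng, training)


class EncoderStage(Module):
    def __init__(self, c_in, c_out, n_convs, dropout, use_se, m, rng):
        self.convs = [ConvBlock(c_in if i == 0 else c_out, c_out, dropout, rng)
                      for i in range(n_convs)]
        self.shortcut = Conv3d(c_in, c_out, k=1, rng=rng) if c_in != c_out else None
        self.se = SELayer(c_out, m=m, rng=rng) if use_se else None
        self.down = Conv3d(c_out, 2 * c_out, k=3, stride=2, padding=1, rng=rng)

    def __call__(self, x, rng, training):
        h = x
        for cb in self.convs:
            h = cb(h, rng, training)
        res = self.shortcut(x) if self.shortcut is not None else x
        h = h + res
        if self.se is not None:
            h = self.se(h)
        return h, ag.relu(self.down(h))  # (skip feature, downsampled)


class DecoderStage(Module):
    def __init__(self, c_in, c_skip, n_convs, dropout, use_agf,
                 radius, epsilon, rng):
        self.up = ConvTranspose3d(c_in, c_skip, rng=rng)
        self.use_agf = use_agf
        if use_agf:
            self.agf = AGFLayer(c_skip, c_in, radius=radius, epsilon=epsilon,
                                rng=rng)
            fuse_in = c_skip + c_in
        else:
            fuse_in = 2 * c_skip  # plain concatenation baseline
        self.convs = [ConvBlock(fuse_in if i == 0 else c_skip, c_skip,
                                dropout, rng) for i in range(n_convs)]

    def __call__(self, x_low, skip, rng, training):
        u = ag.relu(self.up(x_low))
        if self.use_agf:
            fused = ag.concat([u, self.agf(skip, x_low)], axis=-1)
        else:
            fused = ag.concat([u, skip], axis=-1)
        h = fused
        for cb in self.convs:
            h = cb(h, rng, training)
        return h + u  # residual on the upsampled path


class AGSEVNet(Module):
    """Full network; forward maps (N, D, H, W, 4) to softmax probabilities."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config.base_channels
        self.encoders: list[EncoderStage] = []
        c_in = config.input_channels
        chans = []
        for _ in range(config.n_encoder_stages):
            self.encoders.append(EncoderStage(
                c_in, c, config.convs_per_block, config.dropout_rate,
                config.use_se, config.se_reduction, rng))
            chans.append(c)
            c_in, c = 2 * c, 2 * c
        self.bottom = ConvBlock(c_in, c_in, config.dropout_rate, rng)
        self.decoders: list[DecoderStage] = []
        for c_skip in reversed(chans):
            self.decoders.append(DecoderStage(
                2 * c_skip, c_skip, config.convs_per_block,
                config.dropout_rate, config.use_agf,
                config.agf_radius, config.agf_epsilon, rng))
        self.head = Conv3d(chans[0], config.n_classes, k=1, rng=rng)

    def forward(self, x, rng: np.random.Generator | None = None,
                training: bool = False) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        rng = rng or np.random.default_rng(0)
        skips = []
        h = x
        for enc in self.encoders:
            skip, h = enc(h, rng, training)
            skips.append(skip)
        h = self.bottom(h, rng, training)
        for dec, skip in zip(self.decoders, reversed(skips)):
            h = dec(h, skip, rng, training)
        return ag.softmax(self.head(h), axis=-1)

    __call__ = forward

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


def build_network(config: NetworkConfig, seed: int = 0) -> AGSEVNet:
    """Construct the network with deterministic (config, seed) init."""
    return AGSEVNet(config, seed=seed)


# ---------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------

def save_checkpoint(path, model: AGSEVNet, optimizer=None, extra=None) -> None:
    """Single-file .npz checkpoint: weights + config (+ optimizer state)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"param_{i}": p.data for i, p in enumerate(model.parameters())}
    meta = {"config": asdict(model.config), "extra": extra or {}}
    if optimizer is not None:
        state = optimizer.state_dict()
        meta["adam"] = {"t": state["t"], "lr": state["lr"]}
        for i, (m, v) in enumerate(zip(state["m"], state["v"])):
            arrays[f"adam_m_{i}"] = m
            arrays[f"adam_v_{i}"] = v
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path, seed: int = 0):
    """Restore (model, adam_state_or_None, extra) from save_checkpoint."""
    with np.load(Path(path)) as z:
        meta = json.loads(bytes(z["meta_json"].tobytes()).decode())
        cfg = meta["config"]
        cfg["patch_shape"] = tuple(cfg["patch_shape"])
        model = AGSEVNet(NetworkConfig(**cfg), seed=seed)
        params = model.parameters()
        for i, p in enumerate(params):
            p.data = z[f"param_{i}"].copy()
        adam_state = None
        if "adam" in meta:
            adam_state = {
                "t": meta["adam"]["t"],
                "lr": meta["adam"]["lr"],
                "m": [z[f"adam_m_{i}"].copy() for i in range(len(params))],
                "v": [z[f"adam_v_{i}"].copy() for i in range(len(params))],
            }
    return model, adam_state, meta.get("extra", {})
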