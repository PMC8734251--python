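"""Channel squeeze-and-excitation and the attention-guided filter.

These are the two bespoke operators of the architecture. This module
holds the plain-numpy reference implementations (array-in/array-out, no
file I/O); the trainable network layers in :mod:`agsevnet.network` run
the same arithmetic through the autodiff engine and are cross-checked
against these functions in the test suite.

Conventions
-----------
Feature maps are rank-5, channels last: ``(N, D, H, W, C)``.

Squeeze-and-excitation
    ``z_c`` is the global average of channel ``c``; the gate is
    ``s = sigmoid(W2 @ relu(W1 @ z))`` with ``W1`` of shape ``(C/m, C)``
    and ``W2`` of shape ``(C, C/m)``; the recalibrated output is
    ``s_c * u_c``. The reduction factor defaults to ``m = 4``.

Attention-guided filter
    The output is a local linear transform of a high-resolution
    guidance map ``I``: per window ``w_k`` of radius ``r`` the
    coefficients ``(a_k, b_k)`` minimize

        sum_{i in w_k} [ T_i^2 (a_k I_i + b_k - O_i)^2 + eps a_k^2 ]

    where ``T`` is an attention map in (0,1). Per-voxel coefficients
    are the averages of ``(a_k, b_k)`` over every window containing the
    voxel; windows are truncated at volume borders with true in-bounds
    counts. With ``T == 1`` the solution reduces exactly to the
    classical unweighted guided filter. Defaults ``r = 16`` and
    ``eps = 0.1**2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import boxsum3d_np

__all__ = [
    "SEParams",
    "AGFParams",
    "FilterCoefficients",
    "AttentionBlockParams",
    "squeeze",
    "excite",
    "se_block",
    "attention_block",
    "guided_filter_coeffs",
    "guided_filter_coeffs_core",
    "attention_guided_filter",
    "downsample_average",
    "upsample_trilinear_np",
]


# ---------------------------------------------------------------------
# squeeze and excitation
# ---------------------------------------------------------------------

@dataclass
class SEParams:
    """Gating weights of the excitation MLP.

    W1: (C//m, C) first fully connected layer.
    W2: (C, C//m) second fully connected layer.
    """

    W1: np.ndarray
    W2: np.ndarray
    m: int = 4

    def __post_init__(self):
        self.W1 = np.asarray(self.W1, dtype=float)
        self.W2 = np.asarray(self.W2, dtype=float)
        if self.m < 1:
            raise ValueError("reduction factor m must be >= 1")
        c_red, c = self.W1.shape
        if self.W2.shape != (c, c_red):
            raise ValueError(
                f"W2 shape {self.W2.shape} inconsistent with W1 {self.W1.shape}"
            )
        if c % self.m:
            raise ValueError(f"channels C={c} not divisible by m={self.m}")

    @classmethod
    def init(cls, channels: int, m: int = 4,
             rng: np.random.Generator | None = None,
             scale: float = 0.1) -> "SEParams":
        if channels % m:
            raise ValueError(f"channels C={channels} not divisible by m={m}")
        rng = rng or np.random.default_rng(0)
        return cls(
            W1=rng.normal(0.0, scale, size=(channels // m, channels)),
            W2=rng.normal(0.0, scale, size=(channels, channels // m)),
            m=m,
        )


def squeeze(u: np.ndarray) -> np.ndarray:
    """Global average pool: (N, D, H, W, C) -> per-channel descriptor (N, C)."""
    u = np.asarray(u)
    return u.mean(axis=(1, 2, 3))


def excite(z: np.ndarray, params: SEParams) -> np.ndarray:
    """Two-layer gating: s = sigmoid(W2 @ relu(W1 @ z)), entries in (0,1)."""
    z = np.atleast_2d(np.asarray(z, dtype=float))  # (N, C)
    h = np.maximum(z @ params.W1.T, 0.0)
    s = 1.0 / (1.0 + np.exp(-(h @ params.W2.T)))
    return s


def se_block(x: np.ndarray, params: SEParams) -> np.ndarray:
    """Channelwise recalibration x~_c = s_c * u_c; shape preserved."""
    x = np.asarray(x, dtype=float)
    s = excite(squeeze(x), params)  # (N, C)
    return x * s[:, None, None, None, :]


# ---------------------------------------------------------------------
# attention block
# ---------------------------------------------------------------------

@dataclass
class AttentionBlockParams:
    """Weights of the attention block (all convolutions are 1x1x1).

    wo, wi: (C_o, C_mid) and (C_i, C_mid) linear maps applied voxelwise
    to O and I_l; bo, bi their biases; wt: (C_mid, 1) the final map to a
    single-channel attention logit with bias bt.
    """

    wo: np.ndarray
    wi: np.ndarray
    bo: np.ndarray
    bi: np.ndarray
    wt: np.ndarray
    bt: np.ndarray

    @classmethod
    def init(cls, c_o: int, c_i: int, c_mid: int | None = None,
             rng: np.random.Generator | None = None,
             scale: float = 0.1) -> "AttentionBlockParams":
        rng = rng or np.random.default_rng(0)
        c_mid = c_mid or c_o
        return cls(
            wo=rng.normal(0, scale, (c_o, c_mid)),
            wi=rng.normal(0, scale, (c_i, c_mid)),
            bo=np.zeros(c_mid),
            bi=np.zeros(c_mid),
            wt=rng.normal(0, scale, (c_mid, 1)),
            bt=np.zeros(1),
        )


def attention_block(o: np.ndarray, i_l: np.ndarray,
                    params: AttentionBlockParams) -> np.ndarray:
    """Attention map T = sigmoid(conv(relu(conv(O) + conv(I_l)))).

    All convolutions are 1x1x1 so they act voxelwise on the channel
    axis. Output has a single channel; values lie strictly in (0, 1).
    """
    o = np.asarray(o, dtype=float)
    i_l = np.asarray(i_l, dtype=float)
    if o.shape[:4] != i_l.shape[:4]:
        raise ValueError(
            f"spatial mismatch: O {o.shape[:4]} vs I_l {i_l.shape[:4]}"
        )
    h = np.maximum((o @ params.wo + params.bo) + (i_l @ params.wi + params.bi), 0.0)
    t = h @ params.wt + params.bt
    return 1.0 / (1.0 + np.exp(-t))


# ---------------------------------------------------------------------
# guided filter
# ---------------------------------------------------------------------

@dataclass
class AGFParams:
    """Attention-guided-filter hyperparameters.

    r: window radius in voxels; epsilon: ridge regularization added per
    in-window voxel; attention: if False the attention map is ignored
    (T treated as 1), giving the classical guided filter.
    """

    r: int = 16
    epsilon: float = 0.01  # 0.1 ** 2
    attention: bool = True

    def __post_init__(self):
        if self.r < 1:
            raise ValueError("window radius r must be >= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


@dataclass
class FilterCoefficients:
    """Per-voxel linear coefficients of the guided filter, A*I + B."""

    A: np.ndarray
    B: np.ndarray


def guided_filter_coeffs_core(i_l, o, t, r: int, eps: float, boxsum, n,
                              stabilizer: float = 0.0):
    """Backend-generic coefficient computation (numpy arrays or autodiff
    tensors — the arithmetic is expressed through operators and the
    supplied ``boxsum`` callable).

    Solves, per window ``w_k`` with weights ``w_i = T_i^2`` and ridge
    penalty ``|w_k| * eps * a_k^2`` (the per-voxel penalty summed over
    the window), the 2x2 normal equations

        a_k = (S_wIO - S_wI S_wO / S_w) / (S_wII - S_wI^2 / S_w + n eps)
        b_k = (S_wO - a_k S_wI) / S_w

    then averages (a, b) over all windows containing each voxel:
    ``A = boxsum(a)/n``, ``B = boxsum(b)/n`` with ``n`` the in-bounds
    window count. ``stabilizer`` adds a small floor to ``S_w`` (used by
    the trainable layer; zero keeps the math exact for oracle checks).
    """
    w = t * t
    s_w = boxsum(w) + stabilizer
    s_wi = boxsum(w * i_l)
    s_wo = boxsum(w * o)
    s_wii = boxsum(w * i_l * i_l)
    s_wio = boxsum(w * i_l * o)
    a = (s_wio - s_wi * s_wo / s_w) / (s_wii - s_wi * s_wi / s_w + n * eps)
    b = (s_wo - a * s_wi) / s_w
    return boxsum(a) / n, boxsum(b) / n


def _window_counts(shape_sp: tuple[int, int, int], r: int) -> np.ndarray:
    ones = np.ones(shape_sp, dtype=float)
    return boxsum3d_np(ones, r)[None, :, :, :, None]


def guided_filter_coeffs(i_l: np.ndarray, o: np.ndarray,
                         t: np.ndarray | None,
                         params: AGFParams) -> FilterCoefficients:
    """Low-resolution coefficients (A_l, B_l) of the attention-guided
    filter; coefficients are computed per channel of ``O`` against the
    (single-channel) guidance ``i_l``, via broadcasting.
    """
    i_l = np.asarray(i_l, dtype=float)
    o = np.asarray(o, dtype=float)
    if i_l.ndim != 5 or o.ndim != 5:
        raise ValueError("expected rank-5 (N, D, H, W, C) arrays")
    if i_l.shape[:4] != o.shape[:4]:
        raise ValueError(
            f"spatial mismatch: I_l {i_l.shape[:4]} vs O {o.shape[:4]}"
        )
    if t is None or not params.attention:
        t = np.ones(i_l.shape[:4] + (1,), dtype=float)
    else:
        t = np.asarray(t, dtype=float)
    n = _window_counts(i_l.shape[1:4], params.r)
    a, b = guided_filter_coeffs_core(
        i_l, o, t, params.r, params.epsilon,
        boxsum=lambda x: boxsum3d_np(x, params.r), n=n,
    )
    return FilterCoefficients(A=a, B=b)


def downsample_average(x: np.ndarray, factor: int = 2) -> np.ndarray:
    """Average-pool the three spatial axes of a rank-5 array."""
    n, d, h, w, c = x.shape
    f = factor
    if d % f or h % f or w % f:
        raise ValueError(f"spatial dims {(d, h, w)} not divisible by {f}")
    return x.reshape(n, d // f, f, h // f, f, w // f, f, c).mean(axis=(2, 4, 6))


def upsample_trilinear_np(x: np.ndarray, factor: int = 2) -> np.ndarray:
    """Trilinear upsampling (half-pixel convention), numpy path."""
    from .autograd import Tensor, upsample_trilinear3d

    return upsample_trilinear3d(Tensor(np.asarray(x, dtype=float)), factor).data


def attention_guided_filter(i: np.ndarray, o: np.ndarray,
                            params: AGFParams,
                            attn: AttentionBlockParams | None = None,
                            t: np.ndarray | None = None) -> np.ndarray:
    """Full filter: downsample guidance, estimate (A_l, B_l), upsample,
    apply O~ = A_h * I + B_h.

    ``i`` is the high-resolution single-channel guidance (N, D, H, W, 1);
    ``o`` the low-resolution map to be filtered; spatial dims of ``i``
    must be an integer power-of-two multiple of ``o``'s. The attention
    map ``T`` is produced by ``attn`` (an attention block) when given,
    may be passed explicitly via ``t``, and defaults to 1.
    """
    i = np.asarray(i, dtype=float)
    o = np.asarray(o, dtype=float)
    factors = {i.shape[ax] / o.shape[ax] for ax in (1, 2, 3)}
    if len(factors) != 1:
        raise ValueError("anisotropic guidance/output scale factors")
    factor = factors.pop()
    if factor != int(factor) or int(factor) & (int(factor) - 1):
        raise ValueError(
            f"guidance/output scale factor {factor} is not a power-of-two integer"
        )
    factor = int(factor)
    i_l = downsample_average(i, factor) if factor > 1 else i
    if t is None and attn is not None and params.attention:
        t = attention_block(o, i_l, attn)
    coeffs = guided_filter_coeffs(i_l, o, t, params)
    if factor > 1:
        a_h = upsample_trilinear_np(coeffs.A, factor)
        b_h = upsample_trilinear_np(coeffs.B, factor)
    else:
        a_h, b_h = coeffs.A, coeffs.B
    return a_h * i + b_h
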