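"""Omni-dimensional dynamic convolution (ODConv).

A static convolution applies one fixed kernel to every input. ODConv instead
keeps a bank of ``n`` parallel kernels and, for each input sample, predicts
attention values along four dimensions of the kernel tensor — spatial
positions (k x k), input channels, output channels, and the kernel index —
from a squeezed global descriptor of the input. The per-sample effective
kernel is the attention-modulated sum of the bank, so the convolution adapts
to its input while the parameter cost stays that of ``n`` static kernels plus
a small attention head.

Pipeline for the attention head: channel-wise global average pooling ->
squeeze affine (reduction ratio ``gamma``) -> ReLU -> four parallel affine
heads -> sigmoid (the kernel-index head may alternatively use softmax).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, conv2d_per_sample, weighted_kernel_mix
from .nn import Linear, Module, Parameter

__all__ = [
    "KernelBank",
    "OmniAttentionHead",
    "AttentionQuadruple",
    "ODConv2d",
    "compute_attention",
    "effective_kernel",
    "odconv_forward",
    "odconv_param_count",
]


class KernelBank(Module):
    """The ``n`` parallel convolution kernels of one ODConv layer.

    kernels: (n, c_out, c_in, k, k); no convolution bias (normalization
    follows every convolution in the residual block).
    """

    def __init__(self, n: int, c_out: int, c_in: int, k: int, stride: int = 1,
                 padding: int = 0, rng: np.random.Generator | None = None):
        super().__init__()
        if n < 1:
            raise ValueError(f"need at least one kernel, got n={n}")
        if k < 1 or k % 2 == 0:
            raise ValueError(f"kernel size must be odd and positive, got k={k}")
        if stride < 1 or padding < 0:
            raise ValueError("stride must be >= 1 and padding >= 0")
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / (c_in * k * k))
        self.kernels = Parameter(rng.standard_normal((n, c_out, c_in, k, k)) * std)
        self.n, self.c_out, self.c_in, self.k = n, c_out, c_in, k
        self.stride, self.padding = stride, padding


class OmniAttentionHead(Module):
    """Squeeze transform plus the four per-dimension attention heads."""

    def __init__(self, c_in: int, c_out: int, k: int, n: int, gamma: float = 1 / 16,
                 kernel_attention: str = "sigmoid",
                 rng: np.random.Generator | None = None):
        super().__init__()
        if not 0 < gamma <= 1:
            raise ValueError(f"reduction ratio gamma must be in (0, 1], got {gamma}")
        if kernel_attention not in ("sigmoid", "softmax"):
            raise ValueError(f"unknown kernel_attention mode {kernel_attention!r}")
        rng = rng or np.random.default_rng()
        squeezed = max(1, int(c_in * gamma))
        self.c_in, self.c_out, self.k, self.n = c_in, c_out, k, n
        self.gamma, self.squeezed = gamma, squeezed
        self.kernel_attention = kernel_attention
        self.squeeze = Linear(c_in, squeezed, rng=rng)
        self.head_spatial = Linear(squeezed, k * k, rng=rng)
        self.head_in_channel = Linear(squeezed, c_in, rng=rng)
        self.head_out_channel = Linear(squeezed, c_out, rng=rng)
        self.head_kernel = Linear(squeezed, n, rng=rng)


@dataclass
class AttentionQuadruple:
    """Per-sample attention along the four ODConv dimensions.

    spatial: (N, k, k); in_channel: (N, c_in); out_channel: (N, c_out);
    kernel: (N, n). With sigmoid normalization every value lies in (0, 1).
    """

    spatial: Tensor
    in_channel: Tensor
    out_channel: Tensor
    kernel: Tensor

    def numpy(self) -> "AttentionQuadruple":
        return AttentionQuadruple(*(t.data for t in (
            self.spatial, self.in_channel, self.out_channel, self.kernel)))


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def compute_attention(x, head: OmniAttentionHead) -> AttentionQuadruple:
    """Predict the four attention factors from an (N, c_in, H, W) input."""
    x = _as_tensor(x)
    if x.ndim != 4:
        raise ValueError(f"expected a rank-4 input, got shape {x.shape}")
    if x.shape[1] != head.c_in:
        raise ValueError(
            f"channel mismatch: input has {x.shape[1]} channels, "
            f"attention head expects {head.c_in}"
        )
    pooled = x.mean(axis=(2, 3))  # N, c_in
    z = head.squeeze(pooled).relu()
    a_s = head.head_spatial(z).sigmoid().reshape(-1, head.k, head.k)
    a_c = head.head_in_channel(z).sigmoid()
    a_f = head.head_out_channel(z).sigmoid()
    logits_w = head.head_kernel(z)
    if head.kernel_attention == "softmax":
        shifted = logits_w - Tensor(logits_w.data.max(axis=1, keepdims=True))
        e = shifted.exp()
        a_w = e / e.sum(axis=1, keepdims=True)
    else:
        a_w = logits_w.sigmoid()
    return AttentionQuadruple(a_s, a_c, a_f, a_w)


def effective_kernel(attn: AttentionQuadruple, bank: KernelBank) -> Tensor:
    """Aggregate the bank into one kernel per sample: (N, c_out, c_in, k, k).

    W_eff = sum_i kernel[i] * (W_i ⊙ spatial ⊙ in_channel ⊙ out_channel),
    each attention factor broadcast over the dimensions it does not index.
    """
    a_s, a_c = _as_tensor(attn.spatial), _as_tensor(attn.in_channel)
    a_f, a_w = _as_tensor(attn.out_channel), _as_tensor(attn.kernel)
    return weighted_kernel_mix(bank.kernels, a_s, a_c, a_f, a_w)


def odconv_forward(x, bank: KernelBank, head: OmniAttentionHead) -> Tensor:
    """Per-sample dynamic convolution: attention -> effective kernel -> conv."""
    x = _as_tensor(x)
    attn = compute_attention(x, head)
    kernels = effective_kernel(attn, bank)
    return conv2d_per_sample(x, kernels, bank.stride, bank.padding)


def odconv_param_count(bank: KernelBank, head: OmniAttentionHead) -> int:
    """Closed-form trainable-scalar count of one ODConv layer."""
    n, c_out, c_in, k = bank.n, bank.c_out, bank.c_in, bank.k
    sq = head.squeezed
    kernels = n * c_out * c_in * k * k
    squeeze = c_in * sq + sq
    heads = (
        sq * k * k + k * k
        + sq * c_in + c_in
        + sq * c_out + c_out
        + sq * n + n
    )
    return kernels + squeeze + heads


class ODConv2d(Module):
    """ODConv as a drop-in convolution layer (no bias)."""

    def __init__(self, c_in: int, c_out: int, kernel_size: int, stride: int = 1,
                 padding: int = 0, n: int = 4, gamma: float = 1 / 16,
                 kernel_attention: str = "sigmoid",
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.bank = KernelBank(n, c_out, c_in, kernel_size, stride, padding, rng=rng)
        self.head = OmniAttentionHead(c_in, c_out, kernel_size, n, gamma,
                                      kernel_attention, rng=rng)
        self.c_in, self.c_out, self.kernel_size = c_in, c_out, kernel_size
        self.stride, self.padding = stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return odconv_forward(x, self.bank, self.head)

    def param_count(self) -> int:
        return odconv_param_count(self.bank, self.head)

    def _summary(self, in_shape):
        c, h, w = in_shape
        k, s, p = self.kernel_size, self.stride, self.padding
        n, sq = self.bank.n, self.head.squeezed
        h_out = (h + 2 * p - k) // s + 1
        w_out = (w + 2 * p - k) // s + 1
        conv_macs = h_out * w_out * self.c_out * self.c_in * k * k
        # attention head and kernel aggregation run once per sample
        head_macs = self.c_in * sq + sq * (k * k + self.c_in + self.c_out + n)
        mix_macs = n * self.c_out * self.c_in * k * k
        shape = (self.c_out, h_out, w_out)
        row = ("", f"ODConv2d {k}x{k}/{s} n={n}", self.param_count(),
               conv_macs + head_macs + mix_macs, shape)
        return [row], shape
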