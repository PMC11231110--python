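"""ODConv layer: attention pipeline, kernel aggregation, dynamic convolution.

Oracles here are written straight-line (plain numpy loops / scipy), fully
independent of the autodiff implementation they check.
"""

import numpy as np
import pytest
from scipy.signal import correlate2d

from odfcanet.odconv import (
    AttentionQuadruple,
    KernelBank,
    ODConv2d,
    OmniAttentionHead,
    compute_attention,
    effective_kernel,
    odconv_forward,
    odconv_param_count,
)


def sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def attention_oracle(x, head):
    """Straight-line recomputation: GAP -> squeeze -> ReLU -> heads -> sigmoid."""
    pooled = x.mean(axis=(2, 3))
    z = np.maximum(pooled @ head.squeeze.weight.data.T + head.squeeze.bias.data, 0.0)
    lin = lambda m: z @ m.weight.data.T + m.bias.data
    return (
        sigmoid(lin(head.head_spatial)).reshape(-1, head.k, head.k),
        sigmoid(lin(head.head_in_channel)),
        sigmoid(lin(head.head_out_channel)),
        sigmoid(lin(head.head_kernel)),
    )


def effective_kernel_oracle(a_s, a_c, a_f, a_w, kernels):
    """Quadruple-nested-loop aggregation over (kernel, out, in, u, v)."""
    n_samples = a_w.shape[0]
    n, c_out, c_in, k, _ = kernels.shape
    out = np.zeros((n_samples, c_out, c_in, k, k))
    for s in range(n_samples):
        for i in range(n):
            for o in range(c_out):
                for c in range(c_in):
                    for u in range(k):
                        for v in range(k):
                            out[s, o, c, u, v] += (
                                a_w[s, i] * a_f[s, o] * a_c[s, c]
                                * a_s[s, u, v] * kernels[i, o, c, u, v]
                            )
    return out


def sliding_window_conv(sample, kernel, stride, padding):
    """Materialized-kernel convolution of one sample by sliding-window dot products."""
    c_in, h, w = sample.shape
    c_out, _, k, _ = kernel.shape
    xp = np.pad(sample, ((0, 0), (padding, padding), (padding, padding)))
    h_out = (h + 2 * padding - k) // stride + 1
    w_out = (w + 2 * padding - k) // stride + 1
    out = np.zeros((c_out, h_out, w_out))
    for o in range(c_out):
        for i in range(h_out):
            for j in range(w_out):
                patch = xp[:, i * stride : i * stride + k, j * stride : j * stride + k]
                out[o, i, j] = (patch * kernel[o]).sum()
    return out


class TestComputeAttention:
    def test_zero_input_zero_weights_gives_one_half_everywhere(self):
        head = OmniAttentionHead(c_in=4, c_out=6, k=3, n=2, gamma=0.5)
        for p in head.parameters():
            p.data[...] = 0.0
        attn = compute_attention(np.zeros((2, 4, 5, 5)), head)
        for t in (attn.spatial, attn.in_channel, attn.out_channel, attn.kernel):
            np.testing.assert_array_equal(t.data, 0.5)

    def test_head_output_sizes(self):
        head = OmniAttentionHead(c_in=64, c_out=64, k=3, n=4)
        attn = compute_attention(np.zeros((1, 64, 7, 7)), head)
        assert attn.spatial.shape == (1, 3, 3)        # k*k = 9 values
        assert attn.in_channel.shape == (1, 64)
        assert attn.out_channel.shape == (1, 64)
        assert attn.kernel.shape == (1, 4)

    def test_matches_straight_line_oracle(self, rng):
        head = OmniAttentionHead(c_in=4, c_out=3, k=3, n=2, gamma=0.5,
                                 rng=np.random.default_rng(7))
        x = rng.standard_normal((1, 4, 5, 5))
        attn = compute_attention(x, head)
        for got, want in zip(
            (attn.spatial, attn.in_channel, attn.out_channel, attn.kernel),
            attention_oracle(x, head),
        ):
            np.testing.assert_allclose(got.data, want, atol=1e-6)

    def test_values_in_open_unit_interval(self, rng):
        head = OmniAttentionHead(c_in=8, c_out=8, k=3, n=4, rng=rng)
        x = rng.standard_normal((5, 8, 6, 6)) * 100
        attn = compute_attention(x, head)
        for t in (attn.spatial, attn.in_channel, attn.out_channel, attn.kernel):
            assert np.all(t.data > 0) and np.all(t.data < 1)

    def test_channel_mismatch_reports_both_counts(self):
        head = OmniAttentionHead(c_in=4, c_out=4, k=3, n=2)
        with pytest.raises(ValueError, match="8.*4|4.*8"):
            compute_attention(np.zeros((1, 8, 5, 5)), head)

    def test_softmax_mode_normalizes_kernel_attention(self, rng):
        head = OmniAttentionHead(c_in=4, c_out=4, k=3, n=3,
                                 kernel_attention="softmax", rng=rng)
        attn = compute_attention(rng.standard_normal((4, 4, 5, 5)), head)
        np.testing.assert_allclose(attn.kernel.data.sum(axis=1), 1.0, atol=1e-12)


class TestEffectiveKernel:
    @staticmethod
    def _quadruple(a_s, a_c, a_f, a_w):
        return AttentionQuadruple(*(np.asarray(a) for a in (a_s, a_c, a_f, a_w)))

    def test_selector_weights_pick_single_kernel(self, rng):
        bank = KernelBank(n=2, c_out=3, c_in=2, k=3, rng=rng)
        attn = self._quadruple(np.ones((1, 3, 3)), np.ones((1, 2)),
                               np.ones((1, 3)), np.array([[1.0, 0.0]]))
        out = effective_kernel(attn, bank)
        np.testing.assert_array_equal(out.data[0], bank.kernels.data[0])

    def test_equal_kernels_average_to_themselves(self, rng):
        bank = KernelBank(n=2, c_out=3, c_in=2, k=3, rng=rng)
        bank.kernels.data[1] = bank.kernels.data[0]
        attn = self._quadruple(np.ones((1, 3, 3)), np.ones((1, 2)),
                               np.ones((1, 3)), np.array([[0.5, 0.5]]))
        out = effective_kernel(attn, bank)
        np.testing.assert_allclose(out.data[0], bank.kernels.data[0], atol=1e-12)

    def test_matches_nested_loop_oracle(self, rng):
        bank = KernelBank(n=3, c_out=2, c_in=2, k=1, rng=rng)
        a_s = rng.uniform(0, 1, (2, 1, 1))
        a_c = rng.uniform(0, 1, (2, 2))
        a_f = rng.uniform(0, 1, (2, 2))
        a_w = rng.uniform(0, 1, (2, 3))
        out = effective_kernel(self._quadruple(a_s, a_c, a_f, a_w), bank)
        want = effective_kernel_oracle(a_s, a_c, a_f, a_w, bank.kernels.data)
        np.testing.assert_allclose(out.data, want, atol=1e-10)


class TestODConvForward:
    def test_zero_input_gives_zero_output(self, rng):
        layer = ODConv2d(3, 5, 3, padding=1, n=2, rng=rng)
        out = layer(np.zeros((2, 3, 6, 6)))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_degenerates_to_static_convolution_with_unit_attention(self, rng):
        for case in range(10):
            bank = KernelBank(n=1, c_out=3, c_in=2, k=3, stride=1, padding=1, rng=rng)
            x = rng.standard_normal((2, 2, 6, 6))
            attn = AttentionQuadruple(
                np.ones((2, 3, 3)), np.ones((2, 2)), np.ones((2, 3)), np.ones((2, 1))
            )
            from odfcanet.autodiff import Tensor, conv2d_per_sample

            out = conv2d_per_sample(Tensor(x), effective_kernel(attn, bank), 1, 1).data
            for s in range(2):
                for o in range(3):
                    ref = sum(
                        correlate2d(x[s, c], bank.kernels.data[0, o, c],
                                    mode="same", boundary="fill")
                        for c in range(2)
                    )
                    np.testing.assert_allclose(out[s, o], ref, atol=1e-6)

    def test_matches_sliding_window_oracle(self, rng):
        bank = KernelBank(n=2, c_out=3, c_in=2, k=3, stride=1, padding=1,
                          rng=np.random.default_rng(3))
        head = OmniAttentionHead(c_in=2, c_out=3, k=3, n=2, gamma=1.0,
                                 rng=np.random.default_rng(4))
        x = rng.standard_normal((1, 2, 6, 6))
        out = odconv_forward(x, bank, head).data
        a_s, a_c, a_f, a_w = attention_oracle(x, head)
        kernels = effective_kernel_oracle(a_s, a_c, a_f, a_w, bank.kernels.data)
        want = sliding_window_conv(x[0], kernels[0], stride=1, padding=1)
        np.testing.assert_allclose(out[0], want, atol=1e-6)

    def test_linear_in_input_for_frozen_attention(self, rng):
        """With the attention quadruple held fixed the layer is linear."""
        from odfcanet.autodiff import Tensor, conv2d_per_sample

        bank = KernelBank(n=2, c_out=3, c_in=2, k=3, padding=1, rng=rng)
        attn = AttentionQuadruple(
            rng.uniform(0, 1, (2, 3, 3)), rng.uniform(0, 1, (2, 2)),
            rng.uniform(0, 1, (2, 3)), rng.uniform(0, 1, (2, 2)),
        )
        kern = effective_kernel(attn, bank)
        x1 = rng.standard_normal((2, 2, 5, 5))
        x2 = rng.standard_normal((2, 2, 5, 5))
        f = lambda x: conv2d_per_sample(Tensor(x), kern, 1, 1).data
        np.testing.assert_allclose(
            f(2.0 * x1 + 3.0 * x2), 2.0 * f(x1) + 3.0 * f(x2), atol=1e-5
        )


class TestParamCount:
    def test_closed_form_example(self):
        bank = KernelBank(n=2, c_out=4, c_in=4, k=3)
        head = OmniAttentionHead(c_in=4, c_out=4, k=3, n=2, gamma=0.25)
        assert odconv_param_count(bank, head) == 331

    def test_smallest_case(self):
        bank = KernelBank(n=1, c_out=1, c_in=1, k=1)
        head = OmniAttentionHead(c_in=1, c_out=1, k=1, n=1, gamma=1.0)
        assert odconv_param_count(bank, head) == 11

    @pytest.mark.parametrize("c_in,c_out,k,n,gamma", [(8, 16, 3, 2, 0.25), (6, 6, 1, 3, 0.5)])
    def test_doubling_kernel_count_adds_expected_params(self, c_in, c_out, k, n, gamma):
        def total(n_kernels):
            bank = KernelBank(n=n_kernels, c_out=c_out, c_in=c_in, k=k)
            head = OmniAttentionHead(c_in, c_out, k, n_kernels, gamma)
            return odconv_param_count(bank, head), head.squeezed

        before, squeezed = total(n)
        after, _ = total(2 * n)
        assert after - before == n * c_out * c_in * k * k + (squeezed + 1) * n

    def test_count_matches_registered_scalars(self, rng):
        layer = ODConv2d(8, 16, 3, n=4, gamma=1 / 16, rng=rng)
        assert layer.param_count() == layer.num_parameters()

    def test_invalid_bank_configs_rejected(self):
        with pytest.raises(ValueError):
            KernelBank(n=0, c_out=1, c_in=1, k=3)
        with pytest.raises(ValueError):
            KernelBank(n=1, c_out=1, c_in=1, k=2)  # even kernel
        with pytest.raises(ValueError):
            OmniAttentionHead(4, 4, 3, 1, gamma=0.0)
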