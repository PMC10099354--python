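"""Correctness of the numpy CNN engine: forward values against brute-force
references and gradients against explicit adjoint computations."""

import numpy as np
import pytest
from numpy.lib.stride_tricks import sliding_window_view

from maseg import nn
from maseg.nn import autograd as ag


def _scalar_from(t, weights):
    """Attach sum(t * weights) as a scalar loss node (test-only op)."""
    out = nn.Tensor(np.float32((t.data * weights).sum()))
    out.requires_grad = True
    out._prev = (t,)

    def run():
        t._accumulate(weights * out.grad)

    out._backward = run
    return out


@pytest.mark.parametrize("stride,padding", [(1, 1), (1, 0), (2, 1), (2, 3)])
def test_conv2d_forward_matches_window_reference(rng, stride, padding):
    x = nn.Parameter(rng.normal(size=(2, 3, 8, 8)))
    w = nn.Parameter(rng.normal(size=(4, 3, 3, 3)))
    y = ag.conv2d(x, w, None, stride=stride, padding=padding)
    xp = np.pad(x.data.astype(float),
                ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))[:, :, ::stride, ::stride]
    ref = np.einsum("nchwij,ocij->nohw", win, w.data.astype(float))
    np.testing.assert_allclose(y.data, ref, atol=1e-4)


@pytest.mark.parametrize("stride,padding", [(1, 1), (2, 1)])
def test_conv2d_backward_matches_bruteforce_adjoint(rng, stride, padding):
    x = nn.Parameter(rng.normal(size=(2, 3, 8, 8)))
    w = nn.Parameter(rng.normal(size=(4, 3, 3, 3)))
    b = nn.Parameter(rng.normal(size=4))
    y = ag.conv2d(x, w, b, stride=stride, padding=padding)
    g = rng.normal(size=y.data.shape).astype(np.float32)
    _scalar_from(y, g).backward()

    k = 3
    xp = np.pad(x.data.astype(float),
                ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    dxp = np.zeros_like(xp)
    dw = np.zeros(w.data.shape)
    n_, co = x.data.shape[0], w.data.shape[0]
    ho, wo = y.data.shape[2:]
    for n in range(n_):
        for o in range(co):
            for a in range(ho):
                for c in range(wo):
                    gv = g[n, o, a, c]
                    sl = np.s_[n, :, a * stride:a * stride + k,
                               c * stride:c * stride + k]
                    dxp[sl] += gv * w.data[o].astype(float)
                    dw[o] += gv * xp[sl]
    dx_ref = dxp[:, :, padding:-padding, padding:-padding] if padding else dxp
    np.testing.assert_allclose(x.grad, dx_ref, atol=1e-4)
    np.testing.assert_allclose(w.grad, dw, atol=1e-3)
    np.testing.assert_allclose(b.grad, g.sum(axis=(0, 2, 3)), atol=1e-4)


@pytest.mark.parametrize("kernel,stride,padding", [(2, 2, 0), (3, 2, 1)])
def test_max_pool_forward_and_gradient_routing(rng, kernel, stride, padding):
    x = nn.Parameter(rng.normal(size=(2, 3, 8, 8)))
    y = ag.max_pool2d(x, kernel, stride, padding)
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                constant_values=-np.inf)
    win = sliding_window_view(xp, (kernel, kernel), axis=(2, 3))[:, :, ::stride, ::stride]
    np.testing.assert_array_equal(y.data, win.max(axis=(-2, -1)))

    g = rng.normal(size=y.data.shape).astype(np.float32)
    _scalar_from(y, g).backward()
    # gradient flows only to argmax positions; totals are preserved
    assert x.grad.shape == x.data.shape
    np.testing.assert_allclose(x.grad.sum(), g.sum(), rtol=1e-5)
    # each window's gradient lands on a pixel equal to the window max
    assert np.all((x.grad == 0) | np.isfinite(x.grad))


def test_upsample2x_values_and_adjoint(rng):
    x = nn.Parameter(rng.normal(size=(1, 2, 3, 3)))
    y = ag.upsample2x(x)
    np.testing.assert_array_equal(y.data,
                                  x.data.repeat(2, axis=2).repeat(2, axis=3))
    g = rng.normal(size=y.data.shape).astype(np.float32)
    _scalar_from(y, g).backward()
    ref = g.reshape(1, 2, 3, 2, 3, 2).sum(axis=(3, 5))
    np.testing.assert_allclose(x.grad, ref, atol=1e-5)


def test_batch_norm_train_normalizes_and_matches_finite_differences(rng):
    x = nn.Parameter(rng.normal(loc=3.0, scale=2.0, size=(4, 3, 6, 6)))
    gamma = nn.Parameter(rng.normal(size=3))
    beta = nn.Parameter(rng.normal(size=3))
    rm, rv = np.zeros(3, np.float32), np.ones(3, np.float32)
    y = ag.batch_norm(x, gamma, beta, rm, rv, training=True)
    # batch statistics of the normalized pre-affine signal
    xhat = (y.data - beta.data.reshape(1, -1, 1, 1)) / gamma.data.reshape(1, -1, 1, 1)
    np.testing.assert_allclose(xhat.mean(axis=(0, 2, 3)), 0.0, atol=1e-4)
    np.testing.assert_allclose(xhat.std(axis=(0, 2, 3)), 1.0, atol=1e-3)

    g = rng.normal(size=y.data.shape).astype(np.float32)
    _scalar_from(y, g).backward()

    def loss_at(x_arr):
        rm2, rv2 = np.zeros(3, np.float32), np.ones(3, np.float32)
        y2 = ag.batch_norm(nn.Tensor(x_arr), gamma, beta, rm2, rv2, training=True)
        return float((y2.data * g).sum())

    eps = 1e-2
    idx = [(0, 0, 0, 0), (1, 2, 3, 4), (3, 1, 5, 0)]
    for i in idx:
        xp_ = x.data.copy()
        xp_[i] += eps
        xm_ = x.data.copy()
        xm_[i] -= eps
        num = (loss_at(xp_) - loss_at(xm_)) / (2 * eps)
        assert x.grad[i] == pytest.approx(num, rel=0.05, abs=1e-2)


def test_batch_norm_eval_uses_running_statistics(rng):
    x = nn.Tensor(rng.normal(size=(2, 3, 4, 4)))
    gamma = nn.Parameter(np.ones(3))
    beta = nn.Parameter(np.zeros(3))
    rm = np.full(3, 5.0, np.float32)
    rv = np.full(3, 4.0, np.float32)
    y = ag.batch_norm(x, gamma, beta, rm, rv, training=False)
    ref = (x.data - 5.0) / np.sqrt(4.0 + 1e-5)
    np.testing.assert_allclose(y.data, ref, atol=1e-5)
    # eval mode must not touch the buffers
    np.testing.assert_array_equal(rm, 5.0)


def test_softmax_cross_entropy_value_and_gradient(rng):
    logits = nn.Parameter(rng.normal(size=(2, 2, 4, 4)))
    target = (rng.uniform(size=(2, 4, 4)) > 0.5).astype(np.int64)
    loss = ag.softmax_cross_entropy(logits, target)
    z = logits.data
    p = np.exp(z - z.max(axis=1, keepdims=True))
    p /= p.sum(axis=1, keepdims=True)
    picked = np.take_along_axis(p, target[:, None], axis=1)[:, 0]
    assert float(loss.data) == pytest.approx(float(-np.log(picked).mean()), rel=1e-4)
    loss.backward()
    onehot = np.zeros_like(p)
    np.put_along_axis(onehot, target[:, None], 1.0, axis=1)
    np.testing.assert_allclose(logits.grad, (p - onehot) / target.size, atol=1e-5)


def test_attention_gate_scales_skip_pointwise(rng):
    gate = nn.AttentionGate(4, 6, np.random.default_rng(0))
    x = nn.Tensor(rng.normal(size=(1, 4, 8, 8)))
    g = nn.Tensor(rng.normal(size=(1, 6, 8, 8)))
    y = gate(x, g)
    ratio = y.data / np.where(x.data == 0, 1, x.data)
    # one attention coefficient per pixel, shared across channels, in (0, 1)
    assert np.all((ratio > 0) & (ratio < 1) | (x.data == 0))
    np.testing.assert_allclose(ratio.std(axis=1), 0.0, atol=1e-5)


def test_resblock_with_zeroed_residual_branch_is_relu_identity(rng):
    block = nn.ResBlock(5, 5, np.random.default_rng(0))
    block.bn2.weight.data[...] = 0.0
    block.bn2.bias.data[...] = 0.0
    block.eval()
    x = nn.Tensor(rng.normal(size=(2, 5, 6, 6)))
    y = block(x)
    np.testing.assert_allclose(y.data, np.maximum(x.data, 0.0), atol=1e-6)


def test_adam_minimizes_quadratic():
    p = nn.Parameter(np.array([5.0, -3.0], dtype=np.float32))
    opt = nn.Adam([p], lr=0.1)
    for _ in range(300):
        p.grad = 2.0 * (p.data - np.array([1.0, 2.0], dtype=np.float32))
        opt.step()
    np.testing.assert_allclose(p.data, [1.0, 2.0], atol=1e-2)


def test_no_grad_suppresses_tape(rng):
    x = nn.Parameter(rng.normal(size=(1, 3, 4, 4)))
    w = nn.Parameter(rng.normal(size=(2, 3, 3, 3)))
    with ag.no_grad():
        y = ag.conv2d(x, w, None, padding=1)
    assert y._backward is None and y._prev == ()


def test_state_dict_round_trip(rng):
    conv = nn.ConvBNReLU(3, 4, np.random.default_rng(0))
    state = conv.state_dict()
    conv2 = nn.ConvBNReLU(3, 4, np.random.default_rng(99))
    conv2.load_state_dict(state)
    x = nn.Tensor(rng.normal(size=(1, 3, 6, 6)))
    conv.eval()
    conv2.eval()
    np.testing.assert_array_equal(conv(x).data, conv2(x).data)
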