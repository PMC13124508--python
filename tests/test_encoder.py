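"""Dual-domain patch encoder: filter normalization, oracles, invariances."""

import numpy as np
import pytest

from imtscast.autodiff import Tensor, concat
from imtscast.encoder import (DualDomainEncoder, FusionParams, IFANParams,
                              TimeEmbeddingParams, TTCNParams, fuse_patch,
                              ifan_encode, time_embed, ttcn_encode,
                              ttcn_encode_batch, ttcn_filters)

RNG = np.random.default_rng(42)


def gelu_scalar(x):
    from scipy.stats import norm
    return x * norm.cdf(x)


# ---------------------------------------------------------------------------
# continuous time embedding
# ---------------------------------------------------------------------------

def test_time_embed_zero_params_gives_zero_vector():
    p = TimeEmbeddingParams(6)
    p.omega.data[:] = 0.0
    p.alpha.data[:] = 0.0
    out = time_embed(np.array([0.3, 0.7]), p).data
    np.testing.assert_allclose(out, 0.0, atol=1e-15)


def test_time_embed_channel_structure():
    p = TimeEmbeddingParams(5)
    p.alpha.data[1:] = np.pi / 2
    out = time_embed(np.array([0.0]), p).data[0]
    assert out[0] == pytest.approx(0.0)          # linear channel: w0*0 + 0
    np.testing.assert_allclose(out[1:], 1.0)     # sin(pi/2) = 1


def test_time_embed_gradient_wrt_time_nonzero():
    p = TimeEmbeddingParams(5)
    h = 1e-6
    up = time_embed(np.array([0.4 + h]), p).data
    dn = time_embed(np.array([0.4 - h]), p).data
    assert np.linalg.norm((up - dn) / (2 * h)) > 0.1


# ---------------------------------------------------------------------------
# TTCN
# ---------------------------------------------------------------------------

def test_ttcn_singleton_patch_filters_are_one():
    tp = TimeEmbeddingParams(4)
    p = TTCNParams(d_in=5, d_time=3, d_hidden=4,
                   rng=np.random.default_rng(0))
    out = ttcn_encode(np.array([0.2]), np.array([1.7]), tp, p).data
    # softmax of a singleton forces every filter weight to 1, so every
    # output channel equals the plain sum of the augmented features
    phi = time_embed(np.array([0.2]), tp).data[0]
    z = np.concatenate([phi, [1.7]])
    np.testing.assert_allclose(out, np.full(3, z.sum()), atol=1e-9)


def test_ttcn_filters_normalize_over_observations():
    p = TTCNParams(d_in=6, d_time=4, d_hidden=5,
                   rng=np.random.default_rng(1))
    z = Tensor(RNG.normal(size=(7, 9, 6)))
    valid = RNG.random((7, 9)) > 0.3
    valid[:, 0] = True
    f = ttcn_filters(z, valid, p).data       # (K, B, L, D)
    np.testing.assert_allclose(f.sum(axis=2), 1.0, atol=1e-6)
    assert np.all(f[:, ~valid, :] < 1e-12)


def test_ttcn_three_observation_brute_force_oracle():
    """Scalar re-computation of the meta-filter convolution."""
    rng = np.random.default_rng(5)
    tp = TimeEmbeddingParams(3)
    p = TTCNParams(d_in=4, d_time=2, d_hidden=3, rng=rng)
    times = np.array([0.1, 0.5, 0.9])
    values = np.array([1.0, -2.0, 0.5])
    got = ttcn_encode(times, values, tp, p).data

    # oracle: direct loops over the defining equations
    omega, alpha = tp.omega.data, tp.alpha.data
    z = np.zeros((3, 4))
    for j, (t, v) in enumerate(zip(times, values)):
        z[j, 0] = omega[0] * t + alpha[0]
        z[j, 1] = np.sin(omega[1] * t + alpha[1])
        z[j, 2] = np.sin(omega[2] * t + alpha[2])
        z[j, 3] = v
    expected = np.zeros(2)
    for k in range(2):
        W1, b1 = p.W1.data[k], p.b1.data[k, 0, 0]
        W2, b2 = p.W2.data[k], p.b2.data[k, 0, 0]
        scores = np.array([W2.T @ gelu_scalar(W1.T @ z[j] + b1) + b2
                           for j in range(3)])      # (3, 4)
        e = np.exp(scores - scores.max(axis=0, keepdims=True))
        f = e / e.sum(axis=0, keepdims=True)        # softmax over j per d
        expected[k] = sum(f[j] @ z[j] for j in range(3))
    np.testing.assert_allclose(got, expected, atol=1e-6)


def test_ttcn_parameter_count_independent_of_patch_length():
    p = TTCNParams(d_in=6, d_time=4, d_hidden=5)
    count = sum(t.data.size for t in p.params().values())
    tp = TimeEmbeddingParams(5)
    for L in (1, 7, 50):
        t = np.sort(RNG.uniform(0, 1, L))
        ttcn_encode(t, RNG.normal(size=L), tp, p)
        assert sum(t.data.size for t in p.params().values()) == count


def test_ttcn_rejects_empty_patch():
    tp = TimeEmbeddingParams(4)
    p = TTCNParams(d_in=5, d_time=2, d_hidden=3)
    with pytest.raises(ValueError):
        ttcn_encode(np.array([]), np.array([]), tp, p)


def test_ttcn_padding_never_influences_output():
    tp = TimeEmbeddingParams(4)
    p = TTCNParams(d_in=5, d_time=3, d_hidden=4,
                   rng=np.random.default_rng(2))
    t = np.array([0.1, 0.6])
    v = np.array([1.0, -1.0])
    ref = ttcn_encode(t, v, tp, p).data
    # same patch with two padded slots carrying garbage
    phi = time_embed(np.array([0.1, 0.6, 0.9, 0.2]), tp)
    z = concat([phi, Tensor(np.array([1.0, -1.0, 99.0, -99.0])[:, None])],
               axis=-1).reshape(1, 4, 5)
    valid = np.array([[True, True, False, False]])
    padded = ttcn_encode_batch(z, valid, p).data[0]
    np.testing.assert_allclose(padded, ref, atol=1e-9)


# ---------------------------------------------------------------------------
# IFAN
# ---------------------------------------------------------------------------

def test_ifan_permutation_invariance():
    p = IFANParams(d_value=1, d_p=3, d_pbar=4, n_layers=2,
                   rng=np.random.default_rng(3))
    t = np.array([0.1, 0.4, 0.8, 0.9])
    v = np.array([1.0, -0.5, 2.0, 0.3])
    ref = ifan_encode(t, v, p).data
    perm = np.array([2, 0, 3, 1])
    out = ifan_encode(t[perm], v[perm], p).data
    np.testing.assert_allclose(out, ref, atol=1e-12)


def test_ifan_zero_periodic_weights_give_cos_one_sin_zero():
    p = IFANParams(d_value=1, d_p=3, d_pbar=2, n_layers=1)
    p.layers[0]["Wp"].data[:] = 0.0
    p.layers[0]["Up"].data[:] = 0.0
    out = ifan_encode(np.array([0.2, 0.7]), np.array([5.0, -3.0]), p).data
    np.testing.assert_allclose(out[:3], 1.0, atol=1e-12)   # cos block
    np.testing.assert_allclose(out[3:6], 0.0, atol=1e-12)  # sin block


def test_ifan_single_layer_scalar_oracle():
    """Hand computation of one time-aware Fourier layer on one point."""
    p = IFANParams(d_value=1, d_p=1, d_pbar=1, n_layers=1,
                   rng=np.random.default_rng(4))
    t, v = 0.3, 1.2
    got = ifan_encode(np.array([t]), np.array([v]), p).data
    Wp = p.layers[0]["Wp"].data[0, 0]
    Up = p.layers[0]["Up"].data[0]
    Wb = p.layers[0]["Wpbar"].data[0, 0]
    Vb = p.layers[0]["Vpbar"].data[0]
    Bb = p.layers[0]["Bpbar"].data[0]
    u = Wp * v + Up * t
    expected = [np.cos(u), np.sin(u), gelu_scalar(Bb + Wb * v + Vb * t)]
    np.testing.assert_allclose(got, expected, atol=1e-10)


def test_ifan_output_dimension_and_duplication_invariance():
    p = IFANParams(d_value=1, d_p=4, d_pbar=5, n_layers=2,
                   rng=np.random.default_rng(6))
    assert p.d_out == 2 * 4 + 5
    t = np.array([0.2, 0.6])
    v = np.array([1.0, -1.0])
    ref = ifan_encode(t, v, p).data
    assert ref.shape == (13,)
    # duplicating identical observations leaves the mean pool unchanged
    out = ifan_encode(np.repeat(t, 3), np.repeat(v, 3), p).data
    np.testing.assert_allclose(out, ref, atol=1e-12)


# ---------------------------------------------------------------------------
# fusion
# ---------------------------------------------------------------------------

def test_fusion_identity_weights_concatenate():
    p = FusionParams(2, 3, 5, rng=np.random.default_rng(0))
    p.W.data = np.eye(5)
    p.b.data[:] = 0.0
    ht, hf = Tensor(np.array([1.0, 2.0])), Tensor(np.array([3.0, 4.0, 5.0]))
    out = fuse_patch(ht, hf, p).data
    np.testing.assert_allclose(out, [1, 2, 3, 4, 5])


def test_fusion_zero_inputs_give_bias():
    p = FusionParams(2, 3, 4, rng=np.random.default_rng(1))
    p.b.data = np.arange(4.0)
    out = fuse_patch(Tensor(np.zeros(2)), Tensor(np.zeros(3)), p).data
    np.testing.assert_allclose(out, np.arange(4.0))


def test_fusion_affine_property():
    p = FusionParams(3, 3, 4, rng=np.random.default_rng(2))
    a = Tensor(RNG.normal(size=6))
    b = Tensor(RNG.normal(size=6))
    f = lambda x: fuse_patch(x[:3], x[3:], p).data
    zero = f(Tensor(np.zeros(6)))
    np.testing.assert_allclose(f(a + b) - f(a) - f(b) + zero, 0.0,
                               atol=1e-10)


# ---------------------------------------------------------------------------
# trainability and empty-patch handling
# ---------------------------------------------------------------------------

def test_gradients_reach_time_aware_parameters():
    """omega/alpha (time embedding) and Up/Vpbar (IFAN) must be trainable."""
    enc = DualDomainEncoder(n_scales=2, d_time_embed=4, d_time=3, d_freq=8,
                            d_fused=6, d_hidden=4, n_ifan_layers=1,
                            rng=np.random.default_rng(7))
    values = RNG.normal(size=(3, 4, 1))
    times = np.sort(RNG.uniform(0, 1, (3, 4)), axis=1)
    valid = np.ones((3, 4), dtype=bool)
    out = enc.encode_padded(values, times, valid, 0)
    (out * out).sum().backward()
    for name in ("time.omega", "time.alpha", "ifan.layer0.Up",
                 "ifan.layer0.Vpbar"):
        g = enc.params()[name].grad
        assert g is not None and np.linalg.norm(g) > 1e-10, name


def test_empty_patch_resolves_to_learned_token():
    enc = DualDomainEncoder(n_scales=3, d_time_embed=4, d_time=3, d_freq=8,
                            d_fused=6, d_hidden=4,
                            rng=np.random.default_rng(8))
    values = np.zeros((2, 3, 1))
    times = np.zeros((2, 3))
    valid = np.zeros((2, 3), dtype=bool)
    valid[0, 0] = True
    values[0, 0, 0] = 1.5
    out = enc.encode_padded(values, times, valid, scale_index=1).data
    np.testing.assert_allclose(out[1], enc.empty_tokens.data[1], atol=1e-12)
    assert not np.allclose(out[0], enc.empty_tokens.data[1])
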