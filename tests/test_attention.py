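"""Attention primitives against independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import array_shapes, arrays

from xrattn import (
    apply_attention,
    local_attention,
    resize_bilinear,
    scale_projection,
    sigmoid_map,
)
from xrattn.attention import ScaleHead

rng = np.random.default_rng(77)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def bilinear_oracle(src: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Direct evaluation of half-pixel-center bilinear sampling at every site."""
    h, w, c = src.shape
    out = np.zeros((out_h, out_w, c))
    for oy in range(out_h):
        sy = np.clip((oy + 0.5) * h / out_h - 0.5, 0, h - 1)
        y0 = int(np.floor(sy))
        y1 = min(y0 + 1, h - 1)
        fy = sy - y0
        for ox in range(out_w):
            sx = np.clip((ox + 0.5) * w / out_w - 0.5, 0, w - 1)
            x0 = int(np.floor(sx))
            x1 = min(x0 + 1, w - 1)
            fx = sx - x0
            out[oy, ox] = (
                src[y0, x0] * (1 - fy) * (1 - fx)
                + src[y0, x1] * (1 - fy) * fx
                + src[y1, x0] * fy * (1 - fx)
                + src[y1, x1] * fy * fx
            )
    return out


def conv_oracle(src: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Explicit convolution sum with same zero-padding, stride 1."""
    h, wd, cin = src.shape
    kh, kw, _, cout = w.shape
    pt, pl = (kh - 1) // 2, (kw - 1) // 2
    pad = np.zeros((h + kh - 1, wd + kw - 1, cin))
    pad[pt : pt + h, pl : pl + wd] = src
    out = np.zeros((h, wd, cout))
    for y in range(h):
        for x in range(wd):
            for i in range(kh):
                for j in range(kw):
                    out[y, x] += pad[y + i, x + j] @ w[i, j]
    return out + b


# ---------------------------------------------------------------------------
# sigmoid
# ---------------------------------------------------------------------------

def test_sigmoid_closed_form_values():
    np.testing.assert_allclose(sigmoid_map(np.zeros((2, 2, 1))), 0.5)
    assert sigmoid_map(np.full((1, 1, 1), np.log(3.0)))[0, 0, 0] == pytest.approx(0.75)


def test_sigmoid_rejects_nan():
    bad = np.zeros((2, 2, 1))
    bad[0, 0, 0] = np.nan
    with pytest.raises(FloatingPointError):
        sigmoid_map(bad)


@settings(max_examples=50, deadline=None)
@given(
    arrays(np.float64, array_shapes(min_dims=3, max_dims=3, min_side=1, max_side=5),
           elements=st.floats(-30, 30)),
    st.floats(0.0, 5.0),
)
def test_sigmoid_is_elementwise_monotone(a, delta):
    lo, hi = sigmoid_map(a), sigmoid_map(a + delta)
    assert (hi >= lo).all()
    assert (lo > 0).all() and (lo < 1).all()


# ---------------------------------------------------------------------------
# bilinear resize
# ---------------------------------------------------------------------------

def test_resize_identity_and_constant():
    x = rng.random((5, 4, 2))
    np.testing.assert_allclose(resize_bilinear(x, (5, 4)), x, atol=1e-12)
    const = np.full((3, 3, 1), 0.7)
    np.testing.assert_allclose(resize_bilinear(const, (9, 6)), 0.7)


def test_resize_2x2_to_4x4_matches_direct_formula():
    x = np.array([[0.0, 1.0], [2.0, 3.0]])[..., None]
    np.testing.assert_allclose(resize_bilinear(x, (4, 4)), bilinear_oracle(x, 4, 4), atol=1e-12)


def test_resize_matches_oracle_on_random_small_grids():
    for h, w in [(2, 3), (3, 5), (5, 5), (4, 2), (5, 4)]:
        for oh, ow in [(3, 3), (7, 9), (9, 6), (2, 8), (9, 9)]:
            x = rng.random((h, w, 2))
            np.testing.assert_allclose(
                resize_bilinear(x, (oh, ow)), bilinear_oracle(x, oh, ow), atol=1e-6
            )


def test_resize_stays_within_input_range():
    x = rng.random((6, 6, 1))
    out = resize_bilinear(x, (13, 5))
    assert out.min() >= x.min() - 1e-12 and out.max() <= x.max() + 1e-12


def test_resize_rejects_degenerate_target():
    with pytest.raises(ValueError):
        resize_bilinear(rng.random((3, 3, 1)), (0, 4))


def test_resized_sigmoid_stays_strictly_inside_unit_interval():
    raw = rng.normal(scale=4.0, size=(8, 8, 1))
    out = resize_bilinear(sigmoid_map(raw), (3, 11))
    assert (out > 0).all() and (out < 1).all()


# ---------------------------------------------------------------------------
# scale projection
# ---------------------------------------------------------------------------

def test_projection_shape_contract_and_zero_weights():
    prior = rng.random((8, 8, 1))
    w = np.zeros((1, 1, 1, 16))
    out = scale_projection(prior, w, np.zeros(16))
    assert out.shape == (8, 8, 16)
    np.testing.assert_array_equal(out, 0.0)


def test_projection_is_linear_and_matches_convolution_oracle():
    w = rng.normal(size=(3, 3, 2, 4))
    b = np.zeros(4)
    a = rng.random((3, 3, 2))
    c = rng.random((3, 3, 2))
    pa, pc = scale_projection(a, w, b), scale_projection(c, w, b)
    np.testing.assert_allclose(scale_projection(a + c, w, b), pa + pc, atol=1e-9)
    np.testing.assert_allclose(pa, conv_oracle(a, w, b), atol=1e-9)


def test_projection_rejects_channel_mismatch():
    with pytest.raises(ValueError, match="channels"):
        scale_projection(rng.random((4, 4, 3)), rng.normal(size=(1, 1, 2, 5)))


# ---------------------------------------------------------------------------
# full head and residual gate
# ---------------------------------------------------------------------------

def test_head_composition_equals_manual_three_step_pipeline():
    a_g = rng.normal(size=(16, 16, 1))
    w = rng.normal(size=(1, 1, 1, 8))
    b = rng.normal(size=8)
    feature_shape = (4, 4, 8)
    composed = local_attention(feature_shape, a_g, w, b)
    manual = scale_projection(resize_bilinear(sigmoid_map(a_g), (4, 4)), w, b)
    np.testing.assert_array_equal(composed, manual)
    assert composed.shape == feature_shape


@pytest.mark.parametrize("shape", [(8, 8, 4), (4, 6, 2), (16, 16, 1)])
def test_head_output_matches_feature_shape(shape):
    a_g = rng.normal(size=(16, 16, 1))
    w = rng.normal(size=(1, 1, 1, shape[2]))
    out = local_attention(shape, a_g, w, np.zeros(shape[2]))
    assert out.shape == shape


def test_constant_global_map_gives_spatially_constant_local_attention():
    a_g = np.full((12, 12, 1), 1.3)
    w = rng.normal(size=(1, 1, 1, 5))
    out = local_attention((3, 3, 5), a_g, w, np.zeros(5))
    for ch in range(5):
        assert np.ptp(out[:, :, ch]) < 1e-12


def test_apply_attention_zero_is_bitexact_identity():
    f = rng.normal(size=(5, 5, 3))
    out = apply_attention(f, np.zeros_like(f))
    np.testing.assert_array_equal(out, f)


def test_apply_attention_ones_doubles_exactly():
    f = rng.normal(size=(4, 4, 2))
    np.testing.assert_array_equal(apply_attention(f, np.ones_like(f)), 2 * f)


def test_apply_attention_matches_elementwise_scalar_loop():
    f = rng.normal(size=(3, 3, 2))
    a = rng.normal(size=(3, 3, 2))
    out = apply_attention(f, a)
    for i in range(3):
        for j in range(3):
            for k in range(2):
                assert out[i, j, k] == pytest.approx(a[i, j, k] * f[i, j, k] + f[i, j, k])


def test_apply_attention_rejects_shape_mismatch():
    with pytest.raises(ValueError, match="shape"):
        apply_attention(rng.normal(size=(3, 3, 2)), rng.normal(size=(3, 3, 1)))


def test_scale_head_module_is_deterministic_per_seed():
    r1 = np.random.default_rng(3)
    r2 = np.random.default_rng(3)
    h1 = ScaleHead(1, 4, name="h", rng=r1)
    h2 = ScaleHead(1, 4, name="h", rng=r2)
    np.testing.assert_array_equal(h1.weight.data, h2.weight.data)
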