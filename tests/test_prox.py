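"""The chain fused-lasso prox against closed forms and independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rcfgl import (ChainSignal, fused_lasso_prox_1d, soft_threshold,
                   tv1d_prox, weighted_tv_prox)
from rcfgl.prox import chain_prox_batch

from oracles import chain_objective, chain_prox_dual, chain_subgradient_gap


@pytest.mark.parametrize("x,t,expected", [
    (0.5, 0.2, 0.3),
    (-0.1, 0.2, 0.0),
    (-0.7, 0.2, -0.5),
    (1.3, 0.0, 1.3),
])
def test_soft_threshold_values(x, t, expected):
    assert soft_threshold(x, t) == pytest.approx(expected, abs=1e-15)


def test_soft_threshold_vectorized():
    out = soft_threshold(np.array([0.5, -0.1, 0.0]), 0.2)
    np.testing.assert_allclose(out, [0.3, 0.0, 0.0], atol=1e-15)


class TestTV1D:
    def test_constant_input_unchanged(self):
        np.testing.assert_allclose(tv1d_prox([2.0, 2.0, 2.0], 5.0),
                                   [2.0, 2.0, 2.0])

    def test_pair_moves_toward_mean(self):
        # each endpoint moves min(t, gap/2) toward the mean
        np.testing.assert_allclose(tv1d_prox([0.0, 1.0], 0.2), [0.2, 0.8],
                                   atol=1e-12)

    def test_large_t_flattens_to_mean(self):
        np.testing.assert_allclose(tv1d_prox([0.0, 1.0, 2.0], 10.0),
                                   [1.0, 1.0, 1.0], atol=1e-12)

    def test_mean_preserved(self, rng):
        a = rng.normal(0, 2, 7)
        for t in (0.0, 0.1, 1.0, 50.0):
            assert tv1d_prox(a, t).mean() == pytest.approx(a.mean(), abs=1e-10)

    def test_matches_dual_oracle(self, rng):
        from oracles import tv_prox_dual
        for _ in range(50):
            K = int(rng.integers(1, 8))
            a = rng.normal(0, 2, K)
            t = float(rng.uniform(0, 1.5))
            z = tv1d_prox(a, t)
            zo = tv_prox_dual(a, np.full(max(K - 1, 0), t))
            np.testing.assert_allclose(z, zo, atol=1e-7)


class TestWeightedTV:
    def test_zero_weights_identity(self):
        a = [0.3, -1.0, 2.5]
        np.testing.assert_allclose(weighted_tv_prox(a, 0.7, [0.0, 0.0]), a)

    def test_zero_weight_decouples_segments(self):
        # link 2 has weight 0: (0,1) fuse as a pair, 5 is untouched
        np.testing.assert_allclose(weighted_tv_prox([0.0, 1.0, 5.0], 0.2, [1.0, 0.0]),
                                   [0.2, 0.8, 5.0], atol=1e-12)

    def test_weight_scaling_equivalence(self):
        z1 = weighted_tv_prox([0.0, 1.0], 0.1, [2.0])
        z2 = weighted_tv_prox([0.0, 1.0], 0.2, [1.0])
        np.testing.assert_allclose(z1, z2, atol=1e-12)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            weighted_tv_prox([0.0, 1.0], 0.1, [-1.0])


class TestFusedLassoProx:
    def test_t2_zero_is_soft_threshold(self, rng):
        a = rng.normal(0, 1, 4)
        z = fused_lasso_prox_1d(ChainSignal(a=a, w=np.ones(3), t1=0.3, t2=0.0))
        np.testing.assert_allclose(z, soft_threshold(a, 0.3), atol=1e-14)

    def test_t1_zero_is_weighted_tv(self, rng):
        a = rng.normal(0, 1, 4)
        w = np.array([1.0, 0.5, 2.0])
        z = fused_lasso_prox_1d(ChainSignal(a=a, w=w, t1=0.0, t2=0.4))
        np.testing.assert_allclose(z, weighted_tv_prox(a, 0.4, w), atol=1e-14)

    def test_fuse_then_shrink_pair(self):
        z = fused_lasso_prox_1d(ChainSignal(a=[0.0, 1.0], w=[1.0],
                                            t1=0.1, t2=0.2))
        np.testing.assert_allclose(z, [0.1, 0.7], atol=1e-12)

    def test_k1_reduces_to_soft_threshold(self):
        z = fused_lasso_prox_1d(ChainSignal(a=[0.8], w=[], t1=0.3, t2=9.0))
        assert z[0] == pytest.approx(0.5)

    def test_exact_zeros(self):
        z = fused_lasso_prox_1d(ChainSignal(a=[0.05, -0.08], w=[1.0],
                                            t1=0.5, t2=0.1))
        assert z[0] == 0.0 and z[1] == 0.0

    def test_invalid_chain_rejected(self):
        with pytest.raises(ValueError):
            ChainSignal(a=[1.0, 2.0], w=[1.0, 1.0], t1=0.1, t2=0.1)
        with pytest.raises(ValueError):
            ChainSignal(a=[1.0, 2.0], w=[1.0], t1=-0.1, t2=0.1)


def test_batch_matches_single_chain(rng):
    K, m = 4, 40
    A = rng.normal(0, 1.5, (m, K))
    W = rng.choice([0.0, 0.5, 1.0, 2.0], (m, K - 1))
    Z = chain_prox_batch(A, W, 0.2, 0.3)
    for i in range(0, m, 7):
        zi = fused_lasso_prox_1d(ChainSignal(a=A[i], w=W[i], t1=0.2, t2=0.3))
        np.testing.assert_allclose(Z[i], zi, atol=1e-14)


@settings(deadline=None, max_examples=150, derandomize=True)
@given(st.data())
def test_prox_optimality_certificate(data):
    """The returned chain is the exact minimizer: subgradient conditions hold
    and no oracle solution achieves a lower objective."""
    K = data.draw(st.integers(1, 6))
    a = np.array(data.draw(st.lists(
        st.floats(-5, 5, allow_nan=False), min_size=K, max_size=K)))
    w = np.array(data.draw(st.lists(
        st.sampled_from([0.0, 0.5, 1.0, 2.0]), min_size=K - 1, max_size=K - 1)))
    t1 = data.draw(st.sampled_from([0.0, 0.1, 0.5, 1.0]))
    t2 = data.draw(st.sampled_from([0.0, 0.2, 1.0]))
    z = fused_lasso_prox_1d(ChainSignal(a=a, w=w, t1=t1, t2=t2))
    assert chain_subgradient_gap(z, a, t1, t2, w) <= 1e-9
    zo = chain_prox_dual(a, t1, t2, w)
    assert (chain_objective(z, a, t1, t2, w)
            <= chain_objective(zo, a, t1, t2, w) + 1e-9)
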