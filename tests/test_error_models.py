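"""Neural-network kernel, Gaussian likelihoods and GP mismatch prediction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pulmo_uq.error_models import (
    GPMismatchModel,
    TimeSeriesData,
    build_covariance,
    loglik_correlated,
    loglik_correlated_pointwise,
    loglik_iid,
    mismatch_predict,
    nn_kernel,
)
from pulmo_uq.exceptions import ContractError, DomainError


class TestNNKernel:
    @settings(max_examples=30, deadline=None)
    @given(
        t=st.floats(-1.0, 1.0), tp=st.floats(-1.0, 1.0),
        w=st.floats(1e2, 1e5), b=st.floats(0.5, 500.0),
    )
    def test_symmetry_and_bound(self, t, tp, w, b):
        k = nn_kernel(t, tp, w, b)
        assert k == pytest.approx(nn_kernel(tp, t, w, b), rel=1e-12)
        assert abs(k) <= 1.0

    def test_hand_value_at_origin(self):
        # t = t' = 0: k = (2/pi) asin(2b / (1+2b))
        k = nn_kernel(0.0, 0.0, 5.0e4, 138.0)
        assert k == pytest.approx(
            (2 / math.pi) * math.asin(2 * 138 / 277), rel=1e-12)
        assert k == pytest.approx(0.9458, abs=2e-4)

    def test_saturation_limit(self):
        assert nn_kernel(3.0, 3.0, 1e12, 1e6) == pytest.approx(1.0, abs=1e-5)

    def test_positive_hyperparameters_required(self):
        with pytest.raises(DomainError):
            nn_kernel(0.1, 0.2, -1.0, 10.0)


class TestBuildCovariance:
    def test_vanishing_kernel_leaves_noise(self):
        t = np.linspace(0, 0.1, 8)
        gp = GPMismatchModel(w=1e-12, b=1e-12, sigma_n2=0.3)
        C = build_covariance(t, gp)
        np.testing.assert_allclose(C, 0.3 * np.eye(8), atol=1e-10)

    def test_eigenvalue_floor(self):
        # PSD kernel + diagonal shift: lambda_min(C) >= sigma_n2 (eigensolver
        # oracle on n <= 50)
        t = np.linspace(0, 0.11, 50)
        for w, b in [(1e4, 1.0), (9e4, 500.0), (5e4, 138.0)]:
            gp = GPMismatchModel(w=w, b=b, sigma_n2=0.05)
            C = build_covariance(t, gp)
            lam = np.linalg.eigvalsh(C)
            assert lam.min() >= 0.05 * (1 - 1e-8)

    def test_single_point(self):
        gp = GPMismatchModel(w=5e4, b=138.0, sigma_n2=0.05)
        C = build_covariance(np.array([0.02]), gp)
        assert C.shape == (1, 1)
        assert C[0, 0] == pytest.approx(
            nn_kernel(0.02, 0.02, 5e4, 138.0) + 0.05, rel=1e-12)

    def test_pd_on_long_grids(self):
        t = np.linspace(0, 0.11, 2000)
        gp = GPMismatchModel(w=5e4, b=138.0, sigma_n2=0.05)
        C = build_covariance(t, gp)
        np.linalg.cholesky(C)  # must not raise


def _data(t, y):
    return TimeSeriesData(t=t, y=y, vessel_id=1)


class TestLoglikIid:
    def test_zero_residual(self):
        t = np.linspace(0, 1, 5)
        d = _data(t, np.ones(5))
        assert loglik_iid(d, np.ones(5), 2.0) == pytest.approx(
            -2.5 * math.log(2 * math.pi * 2.0), rel=1e-12)

    def test_hand_value(self):
        d = _data(np.array([0.0, 1.0]), np.array([1.0, -1.0]))
        ll = loglik_iid(d, np.zeros(2), 1.0)
        assert ll == pytest.approx(-(math.log(2 * math.pi) + 1.0), rel=1e-12)
        assert ll == pytest.approx(-2.8379, abs=1e-4)

    def test_mle_variance_is_ssr_over_n(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(40)
        d = _data(np.arange(40.0), y)
        ssr = float(np.sum(y ** 2))
        grid = np.linspace(0.3, 3.0, 400)
        lls = [loglik_iid(d, np.zeros(40), s2) for s2 in grid]
        assert grid[int(np.argmax(lls))] == pytest.approx(ssr / 40, rel=0.02)

    def test_length_mismatch(self):
        d = _data(np.arange(3.0), np.zeros(3))
        with pytest.raises(ContractError):
            loglik_iid(d, np.zeros(4), 1.0)


class TestLoglikCorrelated:
    def test_reduces_to_iid_for_diagonal(self):
        rng = np.random.default_rng(1)
        t = np.linspace(0, 0.11, 32)
        y = rng.standard_normal(32)
        d = _data(t, y)
        s2 = 0.7
        ll_c = loglik_correlated(d, np.zeros(32), s2 * np.eye(32))
        ll_i = loglik_iid(d, np.zeros(32), s2)
        assert ll_c == pytest.approx(ll_i, abs=1e-8)

    def test_two_by_two_hand_value(self):
        d = _data(np.array([0.0, 1.0]), np.array([1.0, 1.0]))
        C = np.array([[2.0, 1.0], [1.0, 2.0]])
        ll = loglik_correlated(d, np.zeros(2), C)
        expected = -math.log(2 * math.pi) - 0.5 * math.log(3.0) - 1.0 / 3.0
        assert ll == pytest.approx(expected, rel=1e-12)

    def test_mahalanobis_scale_invariance(self):
        rng = np.random.default_rng(2)
        t = np.linspace(0, 1, 6)
        r = rng.standard_normal(6)
        A = rng.standard_normal((6, 6))
        C = A @ A.T + 6 * np.eye(6)
        m1 = -2 * loglik_correlated(_data(t, r), np.zeros(6), C) \
            - math.log(np.linalg.det(2 * math.pi * C))
        m2 = -2 * loglik_correlated(_data(t, 2 * r), np.zeros(6), 4 * C) \
            - math.log(np.linalg.det(2 * math.pi * 4 * C))
        assert m1 == pytest.approx(m2, rel=1e-9)

    def test_pointwise_sums_to_joint(self):
        rng = np.random.default_rng(3)
        t = np.linspace(0, 0.11, 24)
        gp = GPMismatchModel(w=5e4, b=138.0, sigma_n2=0.05)
        C = build_covariance(t, gp)
        y = rng.standard_normal(24)
        d = _data(t, y)
        pw = loglik_correlated_pointwise(d, np.zeros(24), C)
        # dense-formula oracle
        sign, logdet = np.linalg.slogdet(2 * math.pi * C)
        joint = -0.5 * logdet - 0.5 * y @ np.linalg.solve(C, y)
        assert pw.sum() == pytest.approx(joint, abs=1e-8)

    def test_block_diagonal_equals_sum(self):
        rng = np.random.default_rng(4)
        t = np.linspace(0, 0.11, 16)
        gp = GPMismatchModel(w=5e4, b=138.0, sigma_n2=0.05)
        C = build_covariance(t, gp)
        ds = [_data(t, rng.standard_normal(16)) for _ in range(3)]
        ms = [np.zeros(16)] * 3
        total = loglik_correlated(ds, ms, [C] * 3)
        parts = sum(loglik_correlated(d, m, C) for d, m in zip(ds, ms))
        assert total == pytest.approx(parts, abs=1e-8)

    def test_whitening_of_generated_noise(self):
        t = np.linspace(0, 0.11, 256)
        gp = GPMismatchModel(w=5e4, b=138.0, sigma_n2=0.05)
        C = build_covariance(t, gp)
        L = np.linalg.cholesky(C)
        rng = np.random.default_rng(5)
        for _ in range(3):
            draw = L @ rng.standard_normal(256)
            z = np.linalg.solve(L, draw)
            assert abs(np.var(z) - 1.0) < 3.0 / math.sqrt(256)


class TestMismatchPredict:
    def test_zero_residual_gives_zero_mean(self):
        t = np.linspace(0, 0.11, 16)
        gp = GPMismatchModel(w=5e4, b=138.0, sigma_n2=0.05)
        d = _data(t, np.sin(t * 50))
        mean, cov = mismatch_predict(d, d.y.copy(), gp, t)
        np.testing.assert_allclose(mean, 0.0, atol=1e-12)

    def test_noise_free_interpolation(self):
        t = np.linspace(0, 0.11, 12)
        gp = GPMismatchModel(w=5e4, b=138.0, sigma_n2=1e-10)
        resid = np.sin(t * 30) * 0.4
        d = _data(t, resid)
        mean, _ = mismatch_predict(d, np.zeros_like(t), gp, t)
        np.testing.assert_allclose(mean, resid, atol=1e-4)

    def test_against_dense_conditioning_oracle(self):
        # direct inverse-based GP conditioning on n <= 10
        t = np.linspace(0, 0.1, 8)
        ts = np.array([0.02, 0.05, 0.2, 1.0])
        gp = GPMismatchModel(w=5e4, b=138.0, sigma_n2=0.05)
        rng = np.random.default_rng(6)
        y = rng.standard_normal(8)
        d = _data(t, y)
        mean, cov = mismatch_predict(d, np.zeros(8), gp, ts)
        C = build_covariance(t, gp)
        Ks = nn_kernel(t[:, None], ts[None, :], gp.w, gp.b)
        Kss = nn_kernel(ts[:, None], ts[None, :], gp.w, gp.b)
        Ci = np.linalg.inv(C)
        np.testing.assert_allclose(mean, Ks.T @ Ci @ y, atol=1e-9)
        np.testing.assert_allclose(cov, Kss - Ks.T @ Ci @ Ks, atol=1e-9)
        # posterior variance never exceeds the prior variance
        assert np.all(np.diag(cov) <= np.diag(Kss) + 1e-12)

    def test_observation_noise_added_on_request(self):
        t = np.linspace(0, 0.1, 8)
        gp = GPMismatchModel(w=5e4, b=138.0, sigma_n2=0.05)
        d = _data(t, np.zeros(8))
        _, cov_f = mismatch_predict(d, np.zeros(8), gp, t)
        _, cov_y = mismatch_predict(d, np.zeros(8), gp, t,
                                    include_noise=True)
        np.testing.assert_allclose(cov_y - cov_f, 0.05 * np.eye(8),
                                   atol=1e-12)
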