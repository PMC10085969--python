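import numpy as np
import pytest

from fusdeconv.hrf import HRFParameters, evaluate_hrf
from fusdeconv.simulate import causal_convolve, generate_ep, zscore_rows
from fusdeconv.structure import (StructureConfig, StructureError,
                                 autocorr_tensor, block_column, btd_model,
                                 dehankelize, empirical_core, hankelize,
                                 lambda_op, toeplitz_block)


class TestHankel:
    def test_explicit_small_layout(self):
        out = hankelize(np.array([[1.0, 2, 3, 4]]), Lp=2)
        np.testing.assert_array_equal(out, [[2, 3, 4], [1, 2, 3]])

    def test_region_major_block_order(self):
        Y = np.array([[1.0, 2, 3], [10.0, 20, 30]])
        out = hankelize(Y, Lp=2)
        np.testing.assert_array_equal(out[:2], [[2, 3], [1, 2]])
        np.testing.assert_array_equal(out[2:], [[20, 30], [10, 20]])

    def test_antidiagonals_constant(self, rng):
        out = hankelize(rng.normal(size=(1, 30)), Lp=5)
        for c in range(out.shape[1] - 1):
            np.testing.assert_allclose(out[1:, c + 1], out[:-1, c])

    def test_window_too_long_rejected(self):
        with pytest.raises(StructureError):
            hankelize(np.ones((1, 4)), Lp=4)

    def test_dehankelize_roundtrip(self, rng):
        y = rng.normal(size=40)
        H = hankelize(y[None], Lp=6)
        rec = dehankelize(H, n_out=40, offset=-(6 - 1))
        np.testing.assert_allclose(rec, y, atol=1e-12)


class TestToeplitz:
    def test_explicit_banded_layout(self):
        out = toeplitz_block(np.array([[1.0, 2.0]]), Lp=2)
        np.testing.assert_array_equal(out, [[1, 2, 0], [0, 1, 2]])

    def test_impulse_block_is_scaled_banded_identity(self):
        cfg = StructureConfig(L=2, M=1, Lp=3, K=3)
        out = block_column(np.array([3.0]), cfg, "artifact")
        expected = 3 * np.eye(3, 5)
        np.testing.assert_array_equal(out, expected)

    def test_convolution_identity_on_model_data(self, rng):
        # Y_hankel = H @ S_hankel exactly for causally generated data
        L, Lp, N = 3, 4, 60
        h = rng.uniform(0.1, 1, L + 1)
        s = rng.normal(size=N)
        y = causal_convolve(h, s)
        cfg = StructureConfig(L=L, M=1, Lp=Lp, K=2)
        H = block_column(h[None], cfg, "task")
        Yh = hankelize(y[None], Lp)
        Sh = hankelize(np.concatenate([np.zeros(L), s])[None], cfg.P)
        assert np.max(np.abs(Yh - H @ Sh)) < 1e-10


class TestAutocorrTensor:
    def test_white_noise_slices(self, rng):
        y = rng.standard_normal((1, 100_000))
        T = autocorr_tensor(hankelize(y, 3), K=3)
        np.testing.assert_allclose(T[0], np.eye(3), atol=0.02)
        # lag-2 slice pairs y(t) with y(t+2): only one diagonal survives
        assert abs(T[2][0, 2] - 1) < 0.02
        assert abs(T[1][0, 0]) < 0.02

    def test_unit_variance_scalar_case(self):
        y = zscore_rows(np.arange(50, dtype=float)[None] ** 1.3)
        T = autocorr_tensor(hankelize(y, 1), K=1)
        assert T[0][0, 0] == pytest.approx(1.0, rel=0.03)

    def test_duplicated_regions_have_equal_blocks(self, rng):
        y = rng.normal(size=30)
        T = autocorr_tensor(hankelize(np.stack([y, y]), 3), K=2)
        np.testing.assert_allclose(T[:, :3, :3], T[:, 3:, :3], atol=1e-12)
        np.testing.assert_allclose(T[:, :3, :3], T[:, 3:, 3:], atol=1e-12)

    def test_lag_zero_slice_symmetric_psd(self, rng):
        T = autocorr_tensor(hankelize(rng.normal(size=(2, 200)), 4), K=3)
        np.testing.assert_allclose(T[0], T[0].T, atol=1e-12)
        assert np.linalg.eigvalsh(T[0]).min() > -1e-10

    def test_excessive_lag_count_rejected(self):
        with pytest.raises(StructureError):
            autocorr_tensor(np.ones((2, 5)), K=5)


class TestLambdaOp:
    def test_impulse_generator_gives_shifted_identities(self):
        z = np.zeros(6)
        z[0] = 1.0
        C = lambda_op(z, (4, 3))
        np.testing.assert_array_equal(C[0], np.eye(4))
        np.testing.assert_array_equal(C[1], np.eye(4, k=1))
        np.testing.assert_array_equal(C[2], np.eye(4, k=2))

    def test_slices_are_toeplitz_and_shifted(self, rng):
        z = rng.normal(size=10)
        C = lambda_op(z, (6, 4))
        for k in range(4):
            for off in range(-5, 6):
                d = np.diagonal(C[k], offset=off)
                assert np.ptp(d) == 0 if d.size else True
            if k:
                np.testing.assert_array_equal(C[k][:, 1:], C[k - 1][:, :-1])

    def test_short_generator_rejected(self):
        with pytest.raises(StructureError):
            lambda_op(np.ones(4), (4, 3))

    def test_matches_empirical_source_autocorrelation(self, rng):
        # lambda built from long-run sample lags approximates the
        # empirical core of the same source
        n = 40_000
        s = rng.standard_normal(n)
        s = s + 0.5 * np.concatenate([[0], s[:-1]])  # MA(1), known r
        cfg = StructureConfig(L=1, M=1, Lp=2, K=2)
        z = np.array([(s[: n - d] @ s[d:]) / n for d in range(cfg.z_len)])
        C_emp = empirical_core(s, cfg)
        C_lam = lambda_op(z, (cfg.P, cfg.K))
        np.testing.assert_allclose(C_lam, C_emp, atol=0.03)


class TestStationaryTensor:
    def test_slices_exactly_toeplitz_block_and_shifted(self, rng):
        from fusdeconv.structure import stationary_autocorr_tensor
        cfg = StructureConfig(L=2, M=2, Lp=4, K=3)
        Y = rng.normal(size=(2, 120))
        T = stationary_autocorr_tensor(Y, cfg)
        for k in range(3):
            for b in range(2):
                for b2 in range(2):
                    blk = T[k, b * 4:(b + 1) * 4, b2 * 4:(b2 + 1) * 4]
                    for off in range(-3, 4):
                        d = np.diagonal(blk, offset=off)
                        assert np.ptp(d) == 0
            if k:
                np.testing.assert_allclose(T[k, :4, 1:4], T[k - 1, :4, :3])

    def test_agrees_with_direct_estimator_asymptotically(self, rng):
        from fusdeconv.structure import stationary_autocorr_tensor
        cfg = StructureConfig(L=1, M=1, Lp=3, K=2)
        y = rng.standard_normal((1, 60_000))
        T_direct = autocorr_tensor(hankelize(y, cfg.Lp), cfg.K)
        T_stat = stationary_autocorr_tensor(y, cfg)
        np.testing.assert_allclose(T_stat, T_direct, atol=0.02)


class TestFactorizationIdentity:
    def test_noiseless_model_tensor_decomposes_exactly(self, rng):
        # uncorrelated sources, exact empirical cores on both sides
        M, L, Lp, K = 2, 2, 3, 3
        cfg = StructureConfig(L=L, M=M, Lp=Lp, K=K)
        ep = generate_ep(n_reps=10, stim_dur=4, rest_range=(4, 8), fs=2.0,
                         rng=rng).vector
        N = ep.size
        art = rng.standard_normal(N)
        taps = np.stack([evaluate_hrf(HRFParameters(1, 4 + m, 2), 0.5, L).values
                         for m in range(M)])
        gains = np.array([0.5, 1.5])
        Y = np.stack([causal_convolve(taps[m], ep) + gains[m] * art
                      for m in range(M)])
        T = autocorr_tensor(hankelize(Y, Lp), K)
        H_t = block_column(taps, cfg, "task")
        H_a = block_column(gains, cfg, "artifact")
        cores = [empirical_core(ep, cfg), empirical_core(art, cfg)]
        model = btd_model(cores, [H_t, H_a])
        # cross-source empirical correlation is the only residual; it is
        # not part of the block model, so remove it explicitly
        pad = np.concatenate([np.zeros(L), ep])
        pad2 = np.concatenate([np.zeros(L), art])
        Se, Sa = hankelize(pad[None], cfg.P), hankelize(pad2[None], cfg.P)
        C = Se.shape[1]
        cross = np.stack([Se[:, : C - k] @ Sa[:, k:].T / (C - K)
                          for k in range(K)])
        crossT = np.stack([Sa[:, : C - k] @ Se[:, k:].T / (C - K)
                           for k in range(K)])
        model += np.matmul(np.matmul(H_t, cross), H_a.T)
        model += np.matmul(np.matmul(H_a, crossT), H_t.T)
        rel = np.linalg.norm(T - model) / np.linalg.norm(T)
        assert rel < 1e-6

    def test_uncorrelated_sources_cross_blocks_shrink(self, rng):
        # empirical cross-correlation between independent sources decays
        # as 1/sqrt(N)
        norms = []
        for n in (500, 50_000):
            a, b = rng.standard_normal((2, n))
            cfg = StructureConfig(L=1, M=1, Lp=2, K=2)
            Sa = hankelize(np.concatenate([np.zeros(1), a])[None], cfg.P)
            Sb = hankelize(np.concatenate([np.zeros(1), b])[None], cfg.P)
            C = Sa.shape[1]
            cross = Sa[:, : C - 1] @ Sb[:, 1:].T / (C - 2)
            norms.append(np.linalg.norm(cross))
        assert norms[1] < norms[0] / 3
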