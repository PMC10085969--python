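import numpy as np
import pytest

from fusdeconv.simulate import causal_convolve, generate_ep
from fusdeconv.sources import (SourceEstimationError, binarize_source,
                               canonicalize_sign, estimate_sources,
                               truncated_pinv)
from fusdeconv.structure import StructureConfig, block_column, hankelize


class TestTruncatedPinv:
    def test_identity_unchanged(self):
        P, rank = truncated_pinv(np.eye(4), rel_tol=0.5)
        np.testing.assert_allclose(P, np.eye(4))
        assert rank == 4

    def test_small_singular_value_zeroed(self):
        A = np.diag([1.0, 1e-6])
        P, rank = truncated_pinv(A, rel_tol=0.05)
        np.testing.assert_allclose(P, np.diag([1.0, 0.0]))
        assert rank == 1

    def test_moore_penrose_property_full_rank(self, rng):
        A = rng.normal(size=(8, 5)) + np.eye(8, 5) * 3
        P, _ = truncated_pinv(A, rel_tol=0.0)
        np.testing.assert_allclose(P @ A, np.eye(5), atol=1e-8)

    def test_explicit_discard_count(self, rng):
        A = rng.normal(size=(6, 6))
        _, rank = truncated_pinv(A, discard=2)
        assert rank == 4

    def test_truncation_monotone_in_tolerance(self, rng):
        A = rng.normal(size=(10, 6))
        ranks = [truncated_pinv(A, rel_tol=e)[1] for e in (0, 0.1, 0.3, 0.9)]
        assert ranks == sorted(ranks, reverse=True)

    def test_everything_discarded_rejected(self):
        with pytest.raises(SourceEstimationError):
            truncated_pinv(np.eye(2), discard=2)


class TestEstimateSources:
    def _noiseless(self, rng, M=3):
        from fusdeconv.simulate import simulate_dataset
        return simulate_dataset(M=M, snr_db=np.inf,
                                rng=np.random.default_rng(11))

    def test_noiseless_recovery_with_true_hrfs(self, noiseless_dataset):
        # un-normalized single-source data: recovery is essentially exact
        # (a tiny tolerance removes the structural null direction coming
        # from h(0) = 0 across all regions)
        ds = noiseless_dataset
        cfg = StructureConfig(L=16, M=3)
        est = estimate_sources(ds.hrf_taps[None], ds.Y_raw, cfg, rel_tol=1e-8)
        s = canonicalize_sign(est[0].series)
        r = np.corrcoef(s[16:], ds.ep.vector[16:])[0, 1]
        assert r > 0.99

    def test_noiseless_recovery_after_z_scoring(self, noiseless_dataset):
        # z-scoring leaves a small constant offset per region; recovery
        # of the paradigm stays near-perfect
        ds = noiseless_dataset
        cfg = StructureConfig(L=16, M=3)
        taps = ds.hrf_taps / ds.Y_raw.std(axis=1)[:, None]
        est = estimate_sources(taps[None], ds.Y, cfg, rel_tol=1e-6)
        s = canonicalize_sign(est[0].series)
        assert np.corrcoef(s[16:], ds.ep.vector[16:])[0, 1] > 0.99

    def test_linearity_in_data(self, noiseless_dataset):
        ds = noiseless_dataset
        cfg = StructureConfig(L=16, M=3)
        a = estimate_sources(ds.hrf_taps[None], ds.Y, cfg)[0].series
        b = estimate_sources(ds.hrf_taps[None], 3.0 * ds.Y, cfg)[0].series
        np.testing.assert_allclose(b, 3.0 * a, rtol=1e-10)

    def test_two_sources_separate(self, rng):
        # task source + strong artifact with true filters: each estimate
        # follows its own source and stays nearly orthogonal to the other
        from fusdeconv.simulate import simulate_dataset
        ds = simulate_dataset(M=3, snr_db=0.0, rng=np.random.default_rng(5))
        cfg = StructureConfig(L=16, M=3)
        sig = ds.Y_raw.std(axis=1)
        est = estimate_sources((ds.hrf_taps / sig[:, None])[None], ds.Y, cfg,
                               gains=(ds.artifact_gains / sig)[None],
                               rel_tol=0.02)
        s_task = canonicalize_sign(est[0].series)
        ep = ds.ep.vector
        art = ds.artifact
        r_own = np.corrcoef(s_task[16:], ep[16:])[0, 1]
        r_art = abs(np.corrcoef(est[1].series[16:], art[16:])[0, 1])
        r_cross = abs(np.corrcoef(s_task[16:], art[16:])[0, 1])
        assert r_own > 0.8
        assert r_art > 0.8
        assert r_cross < 0.35

    def test_reconstruction_identity_noiseless(self, noiseless_dataset):
        # H @ S_hat equals the Hankelized data when no truncation occurs
        # (warm-up columns excluded: their filter history is incomplete)
        ds = noiseless_dataset
        cfg = StructureConfig(L=16, M=3)
        H = block_column(ds.hrf_taps, cfg, "task")
        est = estimate_sources(ds.hrf_taps[None], ds.Y_raw, cfg, rel_tol=0.0)
        Yh = hankelize(ds.Y_raw, cfg.Lp)[:, cfg.L:]
        rel = (np.linalg.norm(H @ est[0].hankel_block - Yh)
               / np.linalg.norm(Yh))
        assert rel < 1e-6

    def test_shape_mismatch_rejected(self, noiseless_dataset):
        cfg = StructureConfig(L=16, M=3)
        with pytest.raises(SourceEstimationError):
            estimate_sources(np.ones((1, 2, 5)), noiseless_dataset.Y, cfg)


class TestBinarize:
    def test_recovers_stimulus_blocks_noiselessly(self, rng):
        ep = generate_ep(n_reps=8, stim_dur=4, rest_range=(10, 15), fs=2.0,
                         rng=np.random.default_rng(3))
        from fusdeconv.hrf import HRFParameters, evaluate_hrf
        h = evaluate_hrf(HRFParameters(1, 6, 3), 0.5, 16).values
        series = causal_convolve(h, ep.vector)
        est = binarize_source(series, fs=2.0, min_separation=8.0)
        # the record ends at the last stimulus offset, so that response
        # is truncated; every fully-observed block must be recovered
        for a, b in zip(ep.onsets[:-1], ep.offsets[:-1]):
            overlap = est.vector[a:b + 8].sum()  # allow the HRF delay
            assert overlap > 0

    def test_constant_series_rejected(self):
        with pytest.raises(SourceEstimationError):
            binarize_source(np.ones(50), fs=2.0)

    def test_close_peaks_merged_by_separation_rule(self):
        x = np.zeros(200)
        x[50] = 1.0
        x[54] = 0.8  # closer than min_separation at fs=2
        est = binarize_source(x, fs=2.0, min_separation=8.0)
        assert est.peak_times.size == 1
        assert est.peak_times[0] == pytest.approx(25.0)


class TestSignCanonicalization:
    def test_known_paradigm_orientation(self):
        ep = np.zeros(100)
        ep[40:60] = 1.0
        series = -(ep - ep.mean())
        flipped = canonicalize_sign(series, ep=ep)
        assert flipped[50] > 0

    def test_blind_skewness_orientation(self, rng):
        s = rng.normal(size=2000)
        s[::50] += 6.0  # sparse upward events
        assert np.array_equal(canonicalize_sign(-s), s)
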