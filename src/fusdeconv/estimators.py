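"""scikit-learn style estimators for the deconvolution pipeline.

`BTDDeconvolver` is the user-facing entry point: ``fit`` takes a
(time x regions) matrix, builds the lagged autocorrelation tensor, runs
the multi-restart structured block-term decomposition and the
stability selection, and exposes the final region HRFs; ``transform``
recovers the source time-series through the truncated-SVD
pseudo-inverse of the fitted mixing blocks. `SVDClutterFilter` wraps
the power-Doppler clutter rejection as a transformer.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .hrf import HRFParameters, measure_hrf
from .preprocess import svd_clutter_filter
from .selection import select_stable
from .solver import run_btd_multi
from .structure import (StructureConfig, autocorr_tensor, hankelize,
                        stationary_autocorr_tensor)


class BTDDeconvolver(TransformerMixin, BaseEstimator):
    """Blind recovery of region HRFs and source signals.

    Models the region time-series as convolutive mixtures of a few
    uncorrelated sources: task sources pass through region-specific
    single-gamma HRFs; artifact sources add directly with per-region
    gains. Fitting decomposes the tensor of lagged autocorrelation
    matrices of the block-Hankelized data into structured block terms,
    restarted ``n_restarts`` times from random initializations, and
    keeps the most stable solution cluster.

    Parameters
    ----------
    fs : sampling rate of the time axis, Hz.
    filter_dur : HRF support in seconds; the filter length L is
        ``round(filter_dur * fs)`` samples (L + 1 taps).
    L, lag_window, n_lags : override L, the per-region Hankel window L'
        (default 2(L+1)) and the number of tensor lags K (default L+1).
    n_task, n_artifact : number of task / artifact sources.
    n_restarts : random restarts of the quasi-Newton descent.
    max_iter, gtol : per-restart optimizer budget and gradient norm stop.
    t_cut : dendrogram cut (seconds, peak-latency space) for selection.
    svd_tol : relative singular-value threshold of the truncated
        pseudo-inverse used by ``transform``.
    selection : "cluster" (stability selection) or "lowest-cost".
    random_state : master seed; all restarts derive from it.

    Attributes
    ----------
    hrf_curves_ : (M, L+1) final (cluster-averaged) HRF taps per region.
    hrf_params_ : list of M `HRFParameters` built from member means.
    peak_latencies_, fwhms_ : (n_task, M) shape descriptors in seconds.
    gains_ : (n_artifact, M) artifact gains of the representative run.
    solutions_ : every restart's `BTDSolution`.
    cluster_report_ : the `ClusterReport` of the selection stage.
    config_ : the `StructureConfig` actually used.
    """

    def __init__(self, fs: float = 2.0, filter_dur: float = 8.0,
                 L: int | None = None, lag_window: int | None = None,
                 n_lags: int | None = None, n_task: int = 1,
                 n_artifact: int = 1, n_restarts: int = 20,
                 max_iter: int = 500, gtol: float = 1e-8,
                 t_cut: float = 0.5, svd_tol: float = 0.05,
                 measure_dt: float = 0.05, pl_floor: float = 0.25,
                 selection: str = "cluster", delay_polish: bool = False,
                 tensor_estimator: str = "direct",
                 random_state: int | None = None):
        self.fs = fs
        self.filter_dur = filter_dur
        self.L = L
        self.lag_window = lag_window
        self.n_lags = n_lags
        self.n_task = n_task
        self.n_artifact = n_artifact
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.gtol = gtol
        self.t_cut = t_cut
        self.svd_tol = svd_tol
        self.measure_dt = measure_dt
        self.pl_floor = pl_floor
        self.selection = selection
        self.delay_polish = delay_polish
        self.tensor_estimator = tensor_estimator
        self.random_state = random_state

    def _make_config(self, M: int) -> StructureConfig:
        L = self.L if self.L is not None else int(round(self.filter_dur * self.fs))
        return StructureConfig(L=L, M=M,
                               Lp=self.lag_window or 0,
                               K=self.n_lags or 0,
                               R_task=self.n_task,
                               R_artifact=self.n_artifact)

    def fit(self, X, y=None):
        """Fit on a (n_times, n_regions) matrix (rows are samples)."""
        X = check_array(X, ensure_min_samples=10)
        Y = X.T  # internal convention: regions x time
        cfg = self._make_config(Y.shape[0])
        dt = 1.0 / self.fs
        if self.tensor_estimator == "stationary":
            T = stationary_autocorr_tensor(Y, cfg)
        elif self.tensor_estimator == "direct":
            T = autocorr_tensor(hankelize(Y, cfg.Lp), cfg.K)
        else:
            raise ValueError(
                f"unknown tensor_estimator {self.tensor_estimator!r}")
        solutions = run_btd_multi(T, cfg, n_runs=self.n_restarts,
                                  seed=self.random_state, dt=dt,
                                  max_iter=self.max_iter, gtol=self.gtol)
        report = select_stable(solutions, t_cut=self.t_cut,
                               measure_dt=self.measure_dt,
                               pl_floor=self.pl_floor)
        if self.selection == "lowest-cost":
            from .selection import lowest_cost_pick
            i = lowest_cost_pick(solutions)
            final = solutions[i].hrf_taps
            rep_run = i
        elif self.selection == "cluster":
            from .selection import finalize_hrfs
            final = finalize_hrfs(report.winner_runs, solutions)
            rep_run = int(report.winner_runs[np.argmin(
                [solutions[j].cost for j in report.winner_runs])])
        else:
            raise ValueError(f"unknown selection {self.selection!r}")

        self.config_ = cfg
        self.solutions_ = solutions
        self.cluster_report_ = report
        self.hrf_curves_ = final[0]
        self.hrf_curves_all_ = final
        self.gains_ = solutions[rep_run].gains
        self.representative_run_ = rep_run
        self.hrf_params_ = [HRFParameters(*report.mean_thetas[0, m])
                            for m in range(cfg.M)]
        pls = np.empty((cfg.R_task, cfg.M))
        fws = np.empty((cfg.R_task, cfg.M))
        for r in range(cfg.R_task):
            for m in range(cfg.M):
                # descriptors of the member-mean parameters on a fine grid;
                # curve vs parameter averaging agree to the cluster spread
                params = HRFParameters(*report.mean_thetas[r, m])
                pls[r, m], fws[r, m], _ = measure_hrf(params, dt=self.measure_dt)
        self.delay_ = 0.0
        if self.delay_polish and self.selection == "cluster":
            # cost-anchored common-delay refinement of each winning
            # member before averaging; reliable in the low-noise regime
            # where the gamma-family anchor dominates the cost
            from .selection import solution_peak_latencies
            from .solver import polish_delay
            taps_acc, pl_acc, deltas = [], [], []
            for i in report.winner_runs:
                delta, shifted, _ = polish_delay(T, cfg, dt,
                                                 solutions[i].thetas,
                                                 solutions[i].gains)
                member_pl = solution_peak_latencies(
                    solutions[i], self.measure_dt).reshape(cfg.R_task, cfg.M)
                taps_acc.append(shifted)
                pl_acc.append(member_pl + delta)
                deltas.append(delta)
            self.delay_ = float(np.mean(deltas))
            self.hrf_curves_all_ = np.mean(taps_acc, axis=0)
            self.hrf_curves_ = self.hrf_curves_all_[0]
            pls = np.maximum(np.mean(pl_acc, axis=0), 0.0)
        self.peak_latencies_ = pls
        self.fwhms_ = fws
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        """Recover source series; returns (n_times, n_task + n_artifact)."""
        check_is_fitted(self, "hrf_curves_")
        from .sources import estimate_sources
        X = check_array(X)
        ests = estimate_sources(self.hrf_curves_all_, X.T, self.config_,
                                gains=self.gains_, rel_tol=self.svd_tol)
        return np.stack([e.series for e in ests], axis=1)

    def estimate_paradigm(self, X, min_separation: float = 8.0):
        """Binarize the first recovered task source into a paradigm."""
        from .sources import binarize_source, canonicalize_sign
        series = canonicalize_sign(self.transform(X)[:, 0])
        return binarize_source(series, self.fs, min_separation=min_separation)


class SVDClutterFilter(TransformerMixin, BaseEstimator):
    """Singular-spectrum clutter rejection for frame ensembles.

    ``transform`` treats the input as a (n_pixels, n_frames) block and
    zeroes the top ``low_frac`` and bottom ``high_frac`` fractions of
    the singular values (counts rounded up).
    """

    def __init__(self, low_frac: float = 0.30, high_frac: float = 0.01):
        self.low_frac = low_frac
        self.high_frac = high_frac

    def fit(self, X, y=None):
        check_array(X)
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        X = check_array(X)
        return svd_clutter_filter(X, self.low_frac, self.high_frac)
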