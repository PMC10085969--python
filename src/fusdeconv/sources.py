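"""Source-signal recovery from estimated HRFs.

With the final HRFs re-organized into the Toeplitz block column H_r,
the Hankelized data satisfy Y_h ≈ H_r S_r for the r-th source, so the
source block is recovered as S_r = H_r^+ Y_h with a truncated-SVD
pseudo-inverse (small singular values of H_r amplify noise and are
discarded). The Hankel structure of the true S_r is restored by
averaging anti-diagonals, yielding one series per source; a binary
estimate of the experimental paradigm follows from peak detection on
the task-source series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import skew

from .structure import StructureConfig, block_column, dehankelize, hankelize


class SourceEstimationError(ValueError):
    pass


@dataclass
class SourceEstimate:
    series: np.ndarray         # length-N source series (t = 0..N-1)
    hankel_block: np.ndarray   # raw S_r, (L+Lp) x (N-Lp+1)
    trunc_rank: int
    kind: str                  # "task" or "artifact"


@dataclass
class EstimatedParadigm:
    vector: np.ndarray         # binary 0/1
    peak_times: np.ndarray     # seconds
    intervals: np.ndarray      # (n, 2) start/end sample of each repetition


def truncated_pinv(A: np.ndarray, rel_tol: float = 0.05,
                   discard: int | None = None) -> tuple[np.ndarray, int]:
    """Moore-Penrose pseudo-inverse with small singular values zeroed.

    Singular values below ``rel_tol * sigma_max`` are discarded, or
    exactly ``discard`` of the smallest when given explicitly. Returns
    (pseudo-inverse, rank kept).
    """
    A = np.asarray(A, float)
    if A.size == 0:
        raise SourceEstimationError("empty matrix")
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    if discard is not None:
        keep = max(0, s.size - int(discard))
    else:
        keep = int(np.sum(s > rel_tol * s[0]))
    if keep == 0:
        raise SourceEstimationError("all singular values discarded")
    inv = np.zeros_like(s)
    inv[:keep] = 1.0 / s[:keep]
    return (Vt.T * inv) @ U.T, keep


def canonicalize_sign(series: np.ndarray, ep: np.ndarray | None = None) -> np.ndarray:
    """Resolve the sign ambiguity of a recovered source.

    With a known paradigm, flip so the mean over stimulus-on samples is
    positive; blindly, flip so the series has positive skewness
    (responses are sparse upward deflections).
    """
    if ep is not None:
        on = np.asarray(ep, bool)[: series.size]
        stat = series[: on.size][on].mean() - series.mean()
    else:
        stat = skew(series)
    return -series if stat < 0 else series


def estimate_sources(final_hrfs: np.ndarray, Y: np.ndarray,
                     cfg: StructureConfig, gains: np.ndarray | None = None,
                     rel_tol: float = 0.05,
                     discard: int | None = None) -> list[SourceEstimate]:
    """Recover each source's series from the data and the final HRFs.

    ``final_hrfs`` is (R_task, M, L+1); ``gains`` (R_artifact, M) adds
    artifact-source estimates. The block columns of every source are
    concatenated into the full mixing matrix [H_1 ... H_R], which is
    pseudo-inverted once (truncated SVD) and applied to the Hankelized
    data; inverting jointly separates the sources, whereas inverting a
    single block column would fold the other sources' contributions
    into the estimate. Each source's Hankel block of rows is collapsed
    to a single series by anti-diagonal averaging and trimmed to
    t = 0..N-1.
    """
    final_hrfs = np.asarray(final_hrfs, float)
    if final_hrfs.ndim == 2:
        final_hrfs = final_hrfs[None]
    if final_hrfs.shape[1:] != (cfg.M, cfg.L + 1):
        raise SourceEstimationError(
            f"final_hrfs must be (R, {cfg.M}, {cfg.L + 1}), got {final_hrfs.shape}")
    Y = np.asarray(Y, float)
    N = Y.shape[1]
    # the first L Hankel columns cover samples with incomplete filter
    # history; they violate the convolution model and their residual is
    # amplified by the pseudo-inverse, so they are excluded
    Yh = hankelize(Y, cfg.Lp)[:, cfg.L:]
    specs = [(final_hrfs[r], "task") for r in range(final_hrfs.shape[0])]
    if gains is not None:
        gains = np.atleast_2d(np.asarray(gains, float))
        specs += [(gains[r], "artifact") for r in range(gains.shape[0])]
    H = np.hstack([block_column(tg, cfg, kind) for tg, kind in specs])
    Hp, rank = truncated_pinv(H, rel_tol=rel_tol, discard=discard)
    S_full = Hp @ Yh
    out: list[SourceEstimate] = []
    for r, (_, kind) in enumerate(specs):
        S = S_full[r * cfg.P:(r + 1) * cfg.P]
        # row i, col c of S estimates s(L+Lp-1+c-i); average, trim to 0..N-1
        series = dehankelize(S, n_out=N, offset=-(cfg.P - 1))
        out.append(SourceEstimate(series=series, hankel_block=S,
                                  trunc_rank=rank, kind=kind))
    return out


def binarize_source(series: np.ndarray, fs: float,
                    min_separation: float = 8.0,
                    rise_drop_frac: float = 0.5,
                    prominence_frac: float = 0.5) -> EstimatedParadigm:
    """Binary paradigm estimate from a recovered task-source series.

    Peaks with prominence >= ``prominence_frac`` times the series SD and
    mutual separation >= ``min_separation`` seconds are detected; each
    repetition's on-interval runs between the first outward crossings of
    ``rise_drop_frac`` times the peak height (relative to the series
    median baseline).
    """
    series = np.asarray(series, float)
    if np.ptp(series) == 0:
        raise SourceEstimationError("constant series cannot be binarized")
    base = np.median(series)
    x = series - base
    peaks, _ = find_peaks(x, prominence=prominence_frac * series.std(),
                          distance=max(1, int(round(min_separation * fs))))
    vector = np.zeros(series.size)
    intervals = []
    if peaks.size == 0:
        warnings.warn("no peaks detected; returning an empty paradigm",
                      RuntimeWarning, stacklevel=2)
    for p in peaks:
        thr = rise_drop_frac * x[p]
        a = p
        while a > 0 and x[a - 1] >= thr:
            a -= 1
        b = p
        while b < x.size - 1 and x[b + 1] >= thr:
            b += 1
        vector[a: b + 1] = 1.0
        intervals.append((a, b + 1))
    return EstimatedParadigm(vector=vector, peak_times=peaks / fs,
                             intervals=np.array(intervals, int).reshape(-1, 2))
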