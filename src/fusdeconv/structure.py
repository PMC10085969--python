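"""Block-Hankel, Toeplitz-block and lagged-autocorrelation structure.

A convolutive mixture y_m(t) = sum_r sum_l h_mr(l) s_r(t-l) becomes the
matrix identity Y = H S once the observations and sources are
re-organized into block-Hankel matrices: each region contributes a block
of Lp lagged copies of its series, and H collects the filters h_mr as
banded Toeplitz blocks of size Lp x (L + Lp). Stacking the empirical
lagged autocorrelation matrices R_y(tau) for tau = 0..K-1 yields a
3-way tensor that decomposes as a sum over sources of
C_r x_1 H_r x_2 H_r, where the core C_r holds the (Toeplitz, lag-
shifted) autocorrelation slices of source r and is generated by a
single vector z_r through the lambda operator implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import toeplitz


class StructureError(ValueError):
    pass


@dataclass(frozen=True)
class StructureConfig:
    """Structural hyperparameters of the decomposition.

    L : filter length minus one (samples); the HRF has L + 1 taps.
    Lp : lag window per region (rows per Hankel block).
    K : number of autocorrelation lags (tensor slices), tau = 0..K-1.
    M : number of regions.
    R_task, R_artifact : number of task / artifact sources.
    """

    L: int
    M: int
    Lp: int = 0
    K: int = 0
    R_task: int = 1
    R_artifact: int = 1

    def __post_init__(self):
        if self.Lp == 0:
            object.__setattr__(self, "Lp", 2 * (self.L + 1))
        if self.K == 0:
            object.__setattr__(self, "K", self.L + 1)
        if self.Lp < 1 or self.K < 1 or self.L < 1 or self.M < 1:
            raise StructureError("L, Lp, K, M must all be >= 1")

    @property
    def P(self) -> int:
        """Columns per Toeplitz block / rows per source Hankel block."""
        return self.L + self.Lp

    @property
    def Q(self) -> int:
        """Rows of the block-Hankel data matrix, M * Lp."""
        return self.M * self.Lp

    @property
    def z_len(self) -> int:
        """Length of a symmetric core generating vector, lags 0..P+K-2."""
        return self.P + self.K - 1


def hankelize(Y: np.ndarray, Lp: int) -> np.ndarray:
    """Stack Lp lagged copies of each region's series (block-Hankel).

    Column c holds [y_m(t), y_m(t-1), ..., y_m(t-Lp+1)] for every region
    m (region-major), with t = Lp-1+c; output is (M*Lp) x (N-Lp+1).
    """
    Y = np.atleast_2d(np.asarray(Y, float))
    M, N = Y.shape
    if Lp >= N:
        raise StructureError(f"Lp={Lp} must be < N={N}")
    C = N - Lp + 1
    out = np.empty((M * Lp, C))
    for m in range(M):
        for i in range(Lp):
            out[m * Lp + i] = Y[m, Lp - 1 - i: N - i]
    return out


def dehankelize(S: np.ndarray, n_out: int | None = None,
                offset: int = 0) -> np.ndarray:
    """Average the anti-diagonal estimates of a (noisy) Hankel block.

    Row i, column c of ``S`` estimates the series at index c - i (up to
    the caller's time origin); entries sharing an index are averaged,
    which is the least-squares projection onto exactly-Hankel matrices.
    Returns the series for indices offset .. offset + n_out - 1
    (default: every reconstructed index from 0 upward). Indices down to
    -(P-1) are reachable with a negative ``offset``.
    """
    S = np.asarray(S, float)
    P, C = S.shape
    t_min, t_max = -(P - 1), C - 1
    sums = np.zeros(t_max - t_min + 1)
    counts = np.zeros_like(sums)
    for i in range(P):
        idx = np.arange(C) - i - t_min
        np.add.at(sums, idx, S[i])
        np.add.at(counts, idx, 1)
    series = sums / counts
    start = -t_min + offset
    if n_out is None:
        return series[start:]
    return series[start: start + n_out]


def toeplitz_block(filters: np.ndarray, Lp: int) -> np.ndarray:
    """Banded Toeplitz blocks of a filter set, stacked region-major.

    ``filters`` is (M, L+1); each block has Lp rows and L+Lp columns
    with row i carrying the taps at columns i..i+L. Output (M*Lp, L+Lp).
    For an artifact source pass impulse taps [a_m, 0, ..., 0].
    """
    filters = np.atleast_2d(np.asarray(filters, float))
    M, L1 = filters.shape
    L = L1 - 1
    P = L + Lp
    out = np.zeros((M * Lp, P))
    for m in range(M):
        first_row = np.zeros(P)
        first_row[:L1] = filters[m]
        first_col = np.zeros(Lp)
        first_col[0] = filters[m, 0]
        out[m * Lp:(m + 1) * Lp] = toeplitz(first_col, first_row)
    return out


def block_column(taps_or_gains: np.ndarray, cfg: StructureConfig,
                 kind: str) -> np.ndarray:
    """H_r for one source: gamma-filter blocks or scaled-impulse blocks."""
    if kind == "task":
        filters = np.asarray(taps_or_gains, float)
        if filters.shape != (cfg.M, cfg.L + 1):
            raise StructureError(
                f"task filters must be {(cfg.M, cfg.L + 1)}, got {filters.shape}")
    elif kind == "artifact":
        gains = np.asarray(taps_or_gains, float).reshape(-1)
        if gains.size != cfg.M:
            raise StructureError(f"need {cfg.M} artifact gains, got {gains.size}")
        filters = np.zeros((cfg.M, cfg.L + 1))
        filters[:, 0] = gains
    else:
        raise StructureError(f"unknown source kind {kind!r}")
    return toeplitz_block(filters, cfg.Lp)


def autocorr_tensor(Yh: np.ndarray, K: int) -> np.ndarray:
    """Stack empirical lagged autocorrelation matrices of Hankel columns.

    Slice k is (1/n_valid) * sum_c y(c) y(c+k)^T with the common divisor
    n_valid = C - K (biased estimator), keeping the K slices jointly
    consistent. Output shape (K, Q, Q); slice 0 is symmetric PSD.
    """
    Yh = np.asarray(Yh, float)
    Q, C = Yh.shape
    if K >= C:
        raise StructureError(f"K={K} exceeds available columns C={C}")
    nv = C - K
    T = np.empty((K, Q, Q))
    for k in range(K):
        T[k] = Yh[:, : C - k] @ Yh[:, k:].T / nv
    return T


def stationary_autocorr_tensor(Y: np.ndarray, cfg: "StructureConfig") -> np.ndarray:
    """Autocorrelation tensor built from per-pair lag correlations.

    Instead of averaging outer products of Hankel columns (whose
    entries at a common lag are estimated over slightly different
    sample windows, breaking the exact Toeplitz-block structure the
    core model assumes), one cross-correlation function per region
    pair is estimated over the full record and the tensor is assembled
    from it: slice k, block (m, m'), entry (i, j) = r_{mm'}(k + i - j).
    Every slice is then exactly Toeplitz-block and the slices are exact
    one-lag shifts, so a solution of the generative model is exactly
    representable — the window inconsistency of the direct estimator
    otherwise surfaces as a systematic latency distortion.
    """
    Y = np.atleast_2d(np.asarray(Y, float))
    M, N = Y.shape
    Lp, K = cfg.Lp, cfg.K
    offs = Lp - 1
    dmax = K - 1 + Lp - 1
    if dmax >= N:
        raise StructureError("record too short for the requested lags")
    r = np.zeros((M, M, offs + dmax + 1))
    for m in range(M):
        for m2 in range(M):
            for d in range(0, dmax + 1):
                r[m, m2, d + offs] = Y[m, : N - d] @ Y[m2, d:] / N
            for d in range(1, offs + 1):
                r[m, m2, offs - d] = Y[m, d:] @ Y[m2, : N - d] / N
    T = np.empty((K, M * Lp, M * Lp))
    i = np.arange(Lp)
    D = i[:, None] - i[None, :]
    for k in range(K):
        for m in range(M):
            for m2 in range(M):
                T[k, m * Lp:(m + 1) * Lp, m2 * Lp:(m2 + 1) * Lp] = \
                    r[m, m2][k + D + offs]
    return T


def _lambda_index(P: int, K: int) -> np.ndarray:
    """|k + i - j| lookup into a symmetric generating vector, (K, P, P)."""
    k = np.arange(K)[:, None, None]
    i = np.arange(P)[None, :, None]
    j = np.arange(P)[None, None, :]
    return np.abs(k + i - j)


def lambda_op(z: np.ndarray, dims: tuple[int, int]) -> np.ndarray:
    """Core tensor of lag-shifted Toeplitz slices from a generating vector.

    ``dims = (P, K)``. Slice k has entry (i, j) = z[|k + i - j|]: slice 0
    is the symmetric Toeplitz matrix generated by z, and each subsequent
    slice is the previous one shifted one lag along the generator.
    """
    z = np.asarray(z, float).reshape(-1)
    P, K = dims
    if z.size < P + K - 1:
        raise StructureError(
            f"generating vector needs >= {P + K - 1} lags, got {z.size}")
    return z[_lambda_index(P, K)]


def empirical_core(s: np.ndarray, cfg: StructureConfig) -> np.ndarray:
    """Empirical core tensor of one source, matching the data estimator.

    Hankelizes the zero-padded source with window P = L + Lp so that its
    columns align with the block-Hankel data columns, then applies the
    same biased common-divisor autocorrelation estimator. On exact model
    data, sum_r C_r x_1 H_r x_2 H_r reproduces the data tensor exactly.
    """
    s = np.asarray(s, float).reshape(-1)
    padded = np.concatenate([np.zeros(cfg.L), s])
    Sh = hankelize(padded, cfg.P)
    return autocorr_tensor(Sh, cfg.K)


def btd_model(cores: list[np.ndarray], columns: list[np.ndarray]) -> np.ndarray:
    """sum_r C_r x_1 H_r x_2 H_r for (K, P, P) cores and (Q, P) columns."""
    out = None
    for C, H in zip(cores, columns):
        term = np.matmul(np.matmul(H, C), H.T)
        out = term if out is None else out + term
    return out
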