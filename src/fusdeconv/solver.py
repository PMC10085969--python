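"""Structured block-term decomposition by quasi-Newton descent.

The decomposition minimizes

    J = || T - sum_{r in task} lambda(z_r) x_1 H_r(theta_r) x_2 H_r(theta_r)
           - sum_{r in artifact} lambda(z_r) x_1 H_r(a_r) x_2 H_r(a_r) ||_F^2

over the gamma-HRF parameters theta (one triple per region per task
source), the artifact gains a, and the symmetric core generating
vectors z_r. Positivity of theta is enforced by optimizing
unconstrained variables u with theta1 = e^u, theta2 = 1 + e^u,
theta3 = e^u (theta2 > 1 additionally guarantees an interior HRF peak
and keeps the lag-0 tap finite). The scale ambiguity between each core
and its mixing column is removed by pinning z_r[0] = 1, i.e. unit
source variance, so the response height is carried by theta (or the
gains). Descent is limited-memory BFGS with analytic gradients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import digamma

from .structure import StructureConfig, _lambda_index, lambda_op, toeplitz_block


class SolverError(RuntimeError):
    pass


@dataclass
class BTDSolution:
    """One restart's local minimizer of the decomposition cost."""

    thetas: np.ndarray            # (R_task, M, 3) gamma parameters
    gains: np.ndarray             # (R_artifact, M)
    cores: list[np.ndarray]       # task cores then artifact cores, z[0] = 1
    cost: float
    n_iter: int
    converged: bool
    init_seed: int | None = None
    failed: bool = False
    hrf_taps: np.ndarray | None = field(default=None)  # (R_task, M, L+1)


# ---------------------------------------------------------------------------
# parameter packing


def _unpack(x: np.ndarray, cfg: StructureConfig):
    M, Rt, Ra, nz = cfg.M, cfg.R_task, cfg.R_artifact, cfg.z_len - 1
    pos = 0
    # clip the unconstrained variables to keep exp() finite; the clip acts
    # as a soft barrier far outside any physiological parameter range
    u = np.clip(x[pos: pos + Rt * M * 3], -40.0, 40.0).reshape(Rt, M, 3)
    pos += Rt * M * 3
    gains = x[pos: pos + Ra * M].reshape(Ra, M); pos += Ra * M
    zs = []
    for _ in range(Rt + Ra):
        z = np.empty(nz + 1)
        z[0] = 1.0
        z[1:] = x[pos: pos + nz]; pos += nz
        zs.append(z)
    thetas = np.empty_like(u)
    eu = np.exp(u)
    thetas[..., 0] = eu[..., 0]
    thetas[..., 1] = 1.0 + eu[..., 1]
    thetas[..., 2] = eu[..., 2]
    return thetas, eu, gains, zs


def pack_parameters(thetas: np.ndarray, gains: np.ndarray,
                    cores: list[np.ndarray], cfg: StructureConfig) -> np.ndarray:
    """Inverse of the solver's internal packing (for warm starts)."""
    thetas = np.asarray(thetas, float).reshape(cfg.R_task, cfg.M, 3)
    if np.any(thetas[..., 1] <= 1):
        raise SolverError("warm-start theta2 must be > 1")
    u = np.empty_like(thetas)
    u[..., 0] = np.log(thetas[..., 0])
    u[..., 1] = np.log(thetas[..., 1] - 1.0)
    u[..., 2] = np.log(thetas[..., 2])
    parts = [u.ravel(), np.asarray(gains, float).ravel()]
    for z in cores:
        z = np.asarray(z, float)
        if abs(z[0] - 1.0) > 1e-12:
            z = z / z[0]
        parts.append(z[1:])
    return np.concatenate(parts)


def _hrf_taps_and_grads(thetas: np.ndarray, eu: np.ndarray, dt: float, L: int):
    """Taps h (.., L+1) and d h / d u for the log-reparametrized thetas."""
    from scipy.special import gammaln
    t = np.arange(L + 1) * dt
    t1 = thetas[..., 0:1]
    t2 = thetas[..., 1:2]
    t3 = thetas[..., 2:3]
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        logt = np.log(t)
        logt0 = np.where(np.isfinite(logt), logt, 0.0)
        h = t1 * np.exp(-gammaln(t2) + t2 * np.log(t3)
                        + (t2 - 1.0) * np.where(t > 0, logt0, 0.0) - t3 * t)
        h[..., 0] = 0.0  # theta2 > 1: the t = 0 tap vanishes
        dh_dt2 = h * (np.log(t3) + logt0 - digamma(t2))
        dh_dt2[..., 0] = 0.0
        dh_dt3 = h * (t2 / t3 - t)
        # chain to u: dtheta/du = theta1, theta2 - 1, theta3 respectively
        dh_du1 = h
        dh_du2 = dh_dt2 * eu[..., 1:2]
        dh_du3 = dh_dt3 * t3
    return h, (dh_du1, dh_du2, dh_du3)


def _diag_sums(G_block: np.ndarray, Lp: int, n_offsets: int) -> np.ndarray:
    """Sum along diagonals 0..n_offsets-1 of a (Lp, L+Lp) block."""
    return np.array([np.trace(G_block, offset=l) for l in range(n_offsets)])


def btd_cost_and_grad(x: np.ndarray, T: np.ndarray, cfg: StructureConfig,
                      dt: float):
    """Cost J and its gradient w.r.t. the packed unconstrained variables."""
    M, Lp, P, K = cfg.M, cfg.Lp, cfg.P, cfg.K
    thetas, eu, gains, zs = _unpack(x, cfg)
    idx = _lambda_index(P, K)

    h, dh = _hrf_taps_and_grads(thetas, eu, dt, cfg.L)  # (Rt, M, L+1)
    columns = []
    for r in range(cfg.R_task):
        columns.append(toeplitz_block(h[r], Lp))
    for r in range(cfg.R_artifact):
        filt = np.zeros((M, cfg.L + 1))
        filt[:, 0] = gains[r]
        columns.append(toeplitz_block(filt, Lp))
    cores = [zs[r][idx] for r in range(len(zs))]

    E = T.astype(float, copy=True)
    HC = []
    for Cr, H in zip(cores, columns):
        HCr = np.matmul(H, Cr)                      # (K, Q, P)
        HC.append(HCr)
        E -= np.matmul(HCr, H.T)
    J = float(np.sum(E * E))
    if not np.isfinite(J):
        return np.inf, np.zeros_like(x)

    grad = np.empty_like(x)
    pos_u, pos_a = 0, cfg.R_task * M * 3
    pos_z = pos_a + cfg.R_artifact * M
    nz = cfg.z_len - 1
    Q = cfg.Q
    # flattened views turn the per-slice contractions into single GEMMs
    E_rows = np.ascontiguousarray(E.transpose(1, 0, 2)).reshape(Q, K * Q)
    Et_rows = np.ascontiguousarray(E.transpose(2, 0, 1)).reshape(Q, K * Q)
    for r, (Cr, H) in enumerate(zip(cores, columns)):
        HCt = np.matmul(H, Cr.transpose(0, 2, 1))   # H @ C_k^T
        G_H = -2.0 * (E_rows @ HCt.reshape(K * Q, P)
                      + Et_rows @ HC[r].reshape(K * Q, P))
        G_C = -2.0 * np.matmul(np.matmul(H.T, E), H)  # (K, P, P)
        gz = np.bincount(idx.ravel(), weights=G_C.ravel(),
                         minlength=cfg.z_len)
        grad[pos_z: pos_z + nz] = gz[1:]
        pos_z += nz
        if r < cfg.R_task:
            dtaps = np.empty((M, cfg.L + 1))
            for m in range(M):
                dtaps[m] = _diag_sums(G_H[m * Lp:(m + 1) * Lp], Lp, cfg.L + 1)
            for m in range(M):
                base = pos_u + (r * M + m) * 3
                grad[base + 0] = float(np.dot(dtaps[m], dh[0][r, m]))
                grad[base + 1] = float(np.dot(dtaps[m], dh[1][r, m]))
                grad[base + 2] = float(np.dot(dtaps[m], dh[2][r, m]))
        else:
            ra = r - cfg.R_task
            for m in range(M):
                grad[pos_a + ra * M + m] = float(
                    np.trace(G_H[m * Lp:(m + 1) * Lp]))
    return J, grad


def btd_cost(T: np.ndarray, thetas: np.ndarray, gains: np.ndarray,
             cores: list[np.ndarray], cfg: StructureConfig,
             dt: float = 0.5) -> float:
    """Decomposition cost at explicit parameters (Frobenius norm squared)."""
    thetas = np.asarray(thetas, float).reshape(cfg.R_task, cfg.M, 3)
    if np.any(thetas <= 0):
        raise SolverError("all theta parameters must be strictly positive")
    from .hrf import gamma_hrf_curve
    t = np.arange(cfg.L + 1) * dt
    columns, core_tensors = [], []
    for r in range(cfg.R_task):
        taps = np.stack([gamma_hrf_curve(thetas[r, m], t) for m in range(cfg.M)])
        columns.append(toeplitz_block(taps, cfg.Lp))
    gains = np.asarray(gains, float).reshape(cfg.R_artifact, cfg.M)
    for r in range(cfg.R_artifact):
        filt = np.zeros((cfg.M, cfg.L + 1))
        filt[:, 0] = gains[r]
        columns.append(toeplitz_block(filt, cfg.Lp))
    for z in cores:
        core_tensors.append(lambda_op(z, (cfg.P, cfg.K)))
    E = np.asarray(T, float).copy()
    for Cr, H in zip(core_tensors, columns):
        E -= np.matmul(np.matmul(H, Cr), H.T)
    return float(np.sum(E * E))


def solve_cores_ls(T: np.ndarray, columns: list[np.ndarray],
                   cfg: StructureConfig, ridge: float = 1e-8) -> list[np.ndarray]:
    """Optimal generating vectors for fixed mixing columns.

    The cost is quadratic in the core generators z_r, so for given
    H_r the joint minimizer solves a small normal-equation system. The
    basis tensor of lag d for source r has slices W_{k-d} + W_{k+d}
    (W_o = H S_o H^T, S_o the o-th shift matrix), so all Gram entries
    reduce to inner products of the precomputed W_o. Generators are
    rescaled afterwards to the canonical z[0] = 1 (scale absorbed by
    the caller's filters, or irrelevant for a warm start).
    """
    P, K, Q = cfg.P, cfg.K, cfg.Q
    nz = cfg.z_len
    R = len(columns)
    # W_o per source, o = -(P-1)..P-1 stored at index o+P-1
    Ws = []
    for H in columns:
        W = np.zeros((2 * P - 1, Q, Q))
        for o in range(P):
            Wo = H[:, : P - o] @ H[:, o:].T
            W[o + P - 1] = Wo
            if o:
                W[P - 1 - o] = Wo.T
        Ws.append(W)

    n = R * nz
    A = np.zeros((n, n))
    b = np.zeros(n)
    Wf = [W.reshape(2 * P - 1, -1) for W in Ws]
    Tf = T.reshape(K, -1)
    d = np.arange(nz)
    # per lag k the basis of generator entry d has W-indices k-d and k+d
    masks = []
    for k in range(K):
        om, op = k - d, k + d
        m1 = np.abs(om) <= P - 1
        m2 = (d > 0) & (np.abs(op) <= P - 1)
        masks.append((m1, om[m1] + P - 1, m2, op[m2] + P - 1))
    for r in range(R):
        TW = Tf @ Wf[r].T          # (K, 2P-1)
        br = np.zeros(nz)
        for k, (m1, i1, m2, i2) in enumerate(masks):
            br[m1] += TW[k, i1]
            br[m2] += TW[k, i2]
        b[r * nz:(r + 1) * nz] = br
        for r2 in range(r, R):
            G12 = Wf[r] @ Wf[r2].T   # (2P-1, 2P-1)
            Ap = np.zeros((nz, nz))
            for m1, i1, m2, i2 in masks:
                Rk = np.zeros((nz, 2 * P - 1))
                Rk[m1] += G12[i1]
                Rk[m2] += G12[i2]
                Ap[:, m1] += Rk[:, i1]
                Ap[:, m2] += Rk[:, i2]
            A[r * nz:(r + 1) * nz, r2 * nz:(r2 + 1) * nz] = Ap
            if r2 != r:
                A[r2 * nz:(r2 + 1) * nz, r * nz:(r + 1) * nz] = Ap.T
    A[np.diag_indices_from(A)] += ridge * max(1.0, np.trace(A) / n)
    try:
        sol = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return [sol[r * nz:(r + 1) * nz] for r in range(R)]


def polish_delay(T: np.ndarray, cfg: StructureConfig, dt: float,
                 thetas: np.ndarray, gains: np.ndarray,
                 delta_grid: np.ndarray | None = None,
                 ) -> tuple[float, np.ndarray, np.ndarray]:
    """Resolve the common-delay ambiguity of a fitted solution.

    Second-order blind deconvolution is invariant to delaying every
    filter of a source while advancing the source itself, so descent
    routinely stalls with all HRFs shifted by a common offset: the
    cost's only anchor is that a time-shifted gamma is not itself a
    gamma, a preference too weak for quasi-Newton steps to follow along
    the near-degenerate valley. This scans that one dimension
    explicitly: for each candidate shift delta, every task HRF curve is
    evaluated at t - delta (zero for t < delta), the cores — in which
    the cost is quadratic — are refit exactly, and the shift with the
    lowest cost wins.

    Returns (delta_star, shifted task taps (R_task, M, L+1), cost
    profile over the grid).
    """
    from .hrf import gamma_hrf_curve
    if delta_grid is None:
        delta_grid = np.arange(-2.0, 2.0 + 1e-9, 0.1)
    thetas = np.asarray(thetas, float).reshape(cfg.R_task, cfg.M, 3)
    gains = np.asarray(gains, float).reshape(cfg.R_artifact, cfg.M)
    t = np.arange(cfg.L + 1) * dt
    art_cols = []
    for r in range(cfg.R_artifact):
        filt = np.zeros((cfg.M, cfg.L + 1))
        filt[:, 0] = gains[r]
        art_cols.append(toeplitz_block(filt, cfg.Lp))

    def taps_at(delta: float) -> np.ndarray:
        ts = np.where(t - delta > 0, t - delta, 0.0)
        taps = np.empty((cfg.R_task, cfg.M, cfg.L + 1))
        for r in range(cfg.R_task):
            for m in range(cfg.M):
                curve = gamma_hrf_curve(thetas[r, m], ts)
                curve[t - delta <= 0] = 0.0
                taps[r, m] = curve
        return taps

    costs = np.empty(delta_grid.size)
    for i, delta in enumerate(delta_grid):
        taps = taps_at(float(delta))
        cols = [toeplitz_block(taps[r], cfg.Lp) for r in range(cfg.R_task)]
        cols += art_cols
        zs = solve_cores_ls(T, cols, cfg)
        cores = [lambda_op(z, (cfg.P, cfg.K)) for z in zs]
        E = T.astype(float, copy=True)
        for Cr, H in zip(cores, cols):
            E -= np.matmul(np.matmul(H, Cr), H.T)
        costs[i] = np.sum(E * E)
    best = int(np.argmin(costs))
    delta_star = float(delta_grid[best])
    return delta_star, taps_at(delta_star), costs


DEFAULT_INIT_RANGES = {"theta2": (1.05, 25.0), "theta3": (1.0, 6.0)}


def random_init(cfg: StructureConfig, rng: np.random.Generator,
                init_ranges: dict | None = None) -> np.ndarray:
    """Random start: theta2, theta3 log-uniform over physiologic ranges,
    theta1 = 1, gains and core generators standard normal."""
    ir = dict(DEFAULT_INIT_RANGES)
    if init_ranges:
        ir.update(init_ranges)
    M, Rt, Ra = cfg.M, cfg.R_task, cfg.R_artifact
    t2 = np.exp(rng.uniform(*np.log(ir["theta2"]), size=(Rt, M)))
    t3 = np.exp(rng.uniform(*np.log(ir["theta3"]), size=(Rt, M)))
    u = np.stack([np.zeros((Rt, M)), np.log(np.maximum(t2 - 1.0, 1e-8)),
                  np.log(t3)], axis=-1)
    gains = rng.standard_normal((Ra, M))
    z_free = rng.standard_normal((Rt + Ra) * (cfg.z_len - 1))
    return np.concatenate([u.ravel(), gains.ravel(), z_free])


def _ls_warm_start(x0: np.ndarray, T: np.ndarray, cfg: StructureConfig,
                   dt: float) -> np.ndarray:
    """Replace the random core generators with their exact least-squares
    optimum for the initial filters; the cost is quadratic in z, so this
    puts each restart straight into the valley of its filter draw. The
    generator scale is pushed into theta1 / the gains to keep z[0] = 1.
    """
    thetas, eu, gains, _ = _unpack(x0, cfg)
    h, _ = _hrf_taps_and_grads(thetas, eu, dt, cfg.L)
    columns = [toeplitz_block(h[r], cfg.Lp) for r in range(cfg.R_task)]
    for r in range(cfg.R_artifact):
        filt = np.zeros((cfg.M, cfg.L + 1))
        filt[:, 0] = gains[r]
        columns.append(toeplitz_block(filt, cfg.Lp))
    zs = solve_cores_ls(T, columns, cfg)
    x = x0.copy()
    nz = cfg.z_len - 1
    pos_z = cfg.R_task * cfg.M * 3 + cfg.R_artifact * cfg.M
    for r, z in enumerate(zs):
        v = z[0]
        if v <= 1e-12 or not np.all(np.isfinite(z)):
            continue  # keep the random generator for this source
        scale = np.sqrt(v)
        if r < cfg.R_task:
            x[(r * cfg.M) * 3:(r + 1) * cfg.M * 3:3] += np.log(scale)
        else:
            ra = r - cfg.R_task
            a0 = cfg.R_task * cfg.M * 3
            x[a0 + ra * cfg.M: a0 + (ra + 1) * cfg.M] *= scale
        x[pos_z + r * nz: pos_z + (r + 1) * nz] = z[1:] / v
    return x


def run_btd_once(T: np.ndarray, cfg: StructureConfig, seed=None,
                 dt: float = 0.5, init: np.ndarray | None = None,
                 init_ranges: dict | None = None, max_iter: int = 500,
                 gtol: float = 1e-8, ls_core_init: bool = True) -> BTDSolution:
    """One quasi-Newton descent of the decomposition cost from a random
    (or supplied) starting point."""
    rng = np.random.default_rng(seed)
    if init is None:
        x0 = random_init(cfg, rng, init_ranges)
        if ls_core_init:
            x0 = _ls_warm_start(x0, T, cfg, dt)
    else:
        x0 = np.asarray(init, float)
    res = minimize(btd_cost_and_grad, x0, args=(T, cfg, dt), jac=True,
                   method="L-BFGS-B",
                   options={"maxiter": max_iter, "gtol": gtol,
                            "ftol": 1e-14, "maxfun": 4 * max_iter})
    thetas, _, gains, zs = _unpack(res.x, cfg)
    failed = not np.isfinite(res.fun)
    h, _ = _hrf_taps_and_grads(*_unpack(res.x, cfg)[:2], dt, cfg.L)
    return BTDSolution(thetas=thetas, gains=gains, cores=zs,
                       cost=float(res.fun), n_iter=int(res.nit),
                       converged=bool(res.success), failed=failed,
                       init_seed=None if seed is None else int(seed),
                       hrf_taps=h)


def run_btd_multi(T: np.ndarray, cfg: StructureConfig, n_runs: int = 20,
                  seed=None, dt: float = 0.5, max_iter: int = 500,
                  gtol: float = 1e-8, init_ranges: dict | None = None,
                  retry_budget: int | None = None) -> list[BTDSolution]:
    """Independent random restarts with per-run derived seeds.

    Failed (non-finite) runs are re-drawn up to a retry budget; if every
    attempt fails a SolverError is raised.
    """
    if n_runs < 2:
        raise SolverError("n_runs must be >= 2")
    if retry_budget is None:
        retry_budget = n_runs
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in
                   ss.spawn(n_runs + retry_budget)]
    solutions: list[BTDSolution] = []
    pool = iter(child_seeds)
    retries = 0
    while len(solutions) < n_runs:
        try:
            s = next(pool)
        except StopIteration:
            break
        sol = run_btd_once(T, cfg, seed=s, dt=dt, max_iter=max_iter,
                           gtol=gtol, init_ranges=init_ranges)
        if sol.failed and retries < retry_budget:
            retries += 1
            continue
        solutions.append(sol)
    if not solutions or all(s.failed for s in solutions):
        raise SolverError("all restarts failed with non-finite costs")
    return solutions
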