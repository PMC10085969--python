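"""Stable-solution selection across random restarts.

The decomposition cost is non-convex, so the solver is restarted many
times. Echoing the Icasso approach for ICA, a reliable estimate is one
that recurs tightly across restarts: high-cost outlier runs are dropped
by Otsu thresholding of the final costs, the remaining runs are
clustered on their HRF peak-latency vectors by complete-linkage
agglomerative clustering, each cluster is scored by its complete
diameter divided by its size, and the minimum-score cluster wins. The
final HRFs are the pointwise means of the winning cluster's curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .hrf import HRFParameters, measure_hrf
from .solver import BTDSolution


class SelectionError(RuntimeError):
    pass


@dataclass
class ClusterReport:
    """Outcome of the restart-stability selection."""

    retained_runs: np.ndarray          # indices into the solution list
    labels: np.ndarray                 # cluster id per retained run
    d_C: dict                          # cluster id -> diameter / size
    n_C: dict                          # cluster id -> member count
    winner: int
    winner_runs: np.ndarray            # solution indices in the winning cluster
    final_hrfs: np.ndarray             # (M, L+1) mean curves (task source 0 first)
    final_hrf_std: np.ndarray          # pointwise SD across members
    mean_thetas: np.ndarray            # (R_task, M, 3) member-mean parameters
    std_thetas: np.ndarray
    peak_latencies: np.ndarray = field(default=None)  # features used (runs x features)

    def to_dict(self) -> dict:
        return {
            "retained_runs": self.retained_runs.tolist(),
            "labels": self.labels.tolist(),
            "d_C": {int(k): float(v) for k, v in self.d_C.items()},
            "n_C": {int(k): int(v) for k, v in self.n_C.items()},
            "winner": int(self.winner),
            "winner_runs": self.winner_runs.tolist(),
            "final_hrfs": self.final_hrfs.tolist(),
            "mean_thetas": self.mean_thetas.tolist(),
        }


def otsu_threshold(values: np.ndarray) -> float:
    """Otsu's between-class-variance threshold, evaluated exactly.

    With only a few dozen restart costs, histogram binning (as in image
    thresholding implementations) can misplace points at the mode
    edges, so the criterion is maximized by an exhaustive sweep over
    all inter-point midpoints instead.
    """
    values = np.sort(np.asarray(values, float))
    n = values.size
    if values[0] == values[-1]:
        return float(values[-1])
    best_t, best_var = values[-1], -np.inf
    for t in (values[:-1] + values[1:]) / 2.0:
        lo, hi = values[values <= t], values[values > t]
        if not lo.size or not hi.size:
            continue
        v = (lo.size / n) * (hi.size / n) * (lo.mean() - hi.mean()) ** 2
        if v > best_var:
            best_var, best_t = v, t
    return float(best_t)


def filter_by_cost(solutions: list[BTDSolution]) -> np.ndarray:
    """Retain the low-cost runs below the Otsu threshold of final costs.

    Failed runs are always excluded. If all costs are equal every run is
    retained (no outliers). Raises if fewer than two solutions exist.
    """
    if len(solutions) < 2:
        raise SelectionError("need at least 2 solutions to filter")
    ok = np.array([not s.failed and np.isfinite(s.cost) for s in solutions])
    costs = np.array([s.cost if f else np.inf for s, f in zip(solutions, ok)])
    finite = np.nonzero(ok)[0]
    if finite.size < 2:
        raise SelectionError("fewer than 2 usable runs after removing failures")
    vals = costs[finite]
    if np.ptp(vals) == 0:
        return finite
    thr = otsu_threshold(vals)
    retained = finite[vals <= thr]
    if retained.size < 2:
        # threshold isolated a single run; keep everything at or below the
        # threshold plus the next-lowest cost runs to remain clusterable
        order = finite[np.argsort(vals)]
        retained = order[: max(2, retained.size)]
    return retained


def solution_peak_latencies(sol: BTDSolution, measure_dt: float = 0.05) -> np.ndarray:
    """PL (seconds) of each estimated HRF, task sources concatenated."""
    Rt, M, _ = sol.thetas.shape
    out = np.empty(Rt * M)
    for r in range(Rt):
        for m in range(M):
            try:
                out[r * M + m] = measure_hrf(
                    HRFParameters(*sol.thetas[r, m]), dt=measure_dt)[0]
            except Exception:
                out[r * M + m] = np.nan
    return out


def cluster_solutions(solutions: list[BTDSolution],
                      retained: np.ndarray | None = None,
                      t_cut: float = 0.5,
                      measure_dt: float = 0.05,
                      pl_floor: float = 0.25) -> ClusterReport:
    """Cluster retained restarts on peak-latency features and pick a winner.

    Complete-linkage agglomerative clustering with Euclidean distances,
    tree cut at ``t_cut`` seconds. Each cluster C is scored
    d_C = (complete diameter of C) / n_C; the minimum wins, ties broken
    by larger membership, then by lower mean cost.

    Runs in which every recovered peak latency falls below ``pl_floor``
    seconds are treated as fully collapsed and excluded before
    clustering: a solution whose task filters all peak
    (near-)instantaneously duplicates the artifact impulse term and is
    not a hemodynamic response, yet such collapsed runs recur almost
    identically across restarts and would otherwise form spuriously
    tight clusters. Runs with only some small latencies are kept —
    genuinely fast regions exist. The floor is skipped if it would
    leave fewer than two runs.
    """
    if retained is None:
        retained = filter_by_cost(solutions)
    retained = np.asarray(retained, int)
    feats = np.stack([solution_peak_latencies(solutions[i], measure_dt)
                      for i in retained])
    bad = np.any(~np.isfinite(feats), axis=1)
    retained, feats = retained[~bad], feats[~bad]
    if retained.size == 0:
        raise SelectionError("no retained run has measurable HRF peaks")
    if pl_floor > 0:
        valid = ~np.all(feats < pl_floor, axis=1)
        if valid.sum() >= 2:
            retained, feats = retained[valid], feats[valid]

    if retained.size == 1:
        labels = np.array([1])
    else:
        Z = linkage(feats, method="complete", metric="euclidean")
        labels = fcluster(Z, t=t_cut, criterion="distance")

    D = squareform(pdist(feats)) if retained.size > 1 else np.zeros((1, 1))
    d_C, n_C, mean_cost = {}, {}, {}
    for cid in np.unique(labels):
        members = np.nonzero(labels == cid)[0]
        diam = float(D[np.ix_(members, members)].max())
        d_C[int(cid)] = diam / members.size
        n_C[int(cid)] = members.size
        mean_cost[int(cid)] = float(np.mean([solutions[retained[i]].cost
                                             for i in members]))
    # a singleton trivially has zero diameter; it cannot demonstrate
    # stability, so singletons only win when no cluster recurs at all
    multi = [c for c in d_C if n_C[c] >= 2]
    candidates = multi if multi else list(d_C)
    winner = min(candidates, key=lambda c: (d_C[c], -n_C[c], mean_cost[c]))
    winner_members = np.nonzero(labels == winner)[0]
    winner_runs = retained[winner_members]

    curves = np.stack([solutions[i].hrf_taps for i in winner_runs])  # (n, Rt, M, L+1)
    thetas = np.stack([solutions[i].thetas for i in winner_runs])
    final = curves.mean(axis=0)
    return ClusterReport(
        retained_runs=retained, labels=labels, d_C=d_C, n_C=n_C,
        winner=int(winner), winner_runs=winner_runs,
        final_hrfs=final[0], final_hrf_std=curves.std(axis=0)[0],
        mean_thetas=thetas.mean(axis=0), std_thetas=thetas.std(axis=0),
        peak_latencies=feats)


def finalize_hrfs(winner_runs: np.ndarray,
                  solutions: list[BTDSolution]) -> np.ndarray:
    """Pointwise mean of the winning cluster's HRF curves, (R_task, M, L+1)."""
    curves = np.stack([solutions[i].hrf_taps for i in np.asarray(winner_runs, int)])
    return curves.mean(axis=0)


def select_stable(solutions: list[BTDSolution], t_cut: float = 0.5,
                  measure_dt: float = 0.05,
                  pl_floor: float = 0.25) -> ClusterReport:
    """Cost filter + clustering + averaging in one call."""
    retained = filter_by_cost(solutions)
    return cluster_solutions(solutions, retained, t_cut, measure_dt, pl_floor)


def lowest_cost_pick(solutions: list[BTDSolution]) -> int:
    """Index of the (non-failed) restart with the smallest final cost."""
    costs = [np.inf if s.failed else s.cost for s in solutions]
    return int(np.argmin(costs))
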