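import numpy as np
import pytest

from fusdeconv.selection import (SelectionError, cluster_solutions,
                                 filter_by_cost, finalize_hrfs,
                                 lowest_cost_pick, otsu_threshold,
                                 select_stable)
from fusdeconv.solver import BTDSolution


def _fake_solution(pls, cost, dt=0.5, L=16, amp=1.0):
    """Solution whose gamma parameters put the HRF peaks at `pls` seconds."""
    thetas = np.array([[[amp, 9.0, 8.0 / max(pl, 1e-3)] for pl in pls]])
    taps = np.zeros((1, len(pls), L + 1))
    from fusdeconv.hrf import HRFParameters, evaluate_hrf
    for m, pl in enumerate(pls):
        taps[0, m] = evaluate_hrf(HRFParameters(*thetas[0, m]), dt, L).values
    return BTDSolution(thetas=thetas, gains=np.zeros((1, len(pls))),
                       cores=[], cost=cost, n_iter=1, converged=True,
                       hrf_taps=taps)


def _sweep_otsu_oracle(vals):
    """Exhaustive threshold sweep maximizing between-class variance."""
    vals = np.sort(np.asarray(vals, float))
    best_t, best_var = vals[0], -1.0
    for t in (vals[:-1] + vals[1:]) / 2:
        lo, hi = vals[vals <= t], vals[vals > t]
        if not lo.size or not hi.size:
            continue
        w0, w1 = lo.size / vals.size, hi.size / vals.size
        v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if v > best_var:
            best_var, best_t = v, t
    return best_t


class TestCostFilter:
    def test_clear_outlier_dropped(self):
        sols = [_fake_solution([1, 2, 3], c) for c in (1.0, 1.0, 1.0, 100.0)]
        np.testing.assert_array_equal(filter_by_cost(sols), [0, 1, 2])

    def test_equal_costs_retain_all(self):
        sols = [_fake_solution([1, 2, 3], 5.0) for _ in range(4)]
        np.testing.assert_array_equal(filter_by_cost(sols), [0, 1, 2, 3])

    def test_two_gaussian_modes_match_sweep_oracle(self, rng):
        lo = rng.normal(1.0, 0.05, 12)
        hi = rng.normal(10.0, 0.5, 8)
        costs = np.concatenate([lo, hi])
        sols = [_fake_solution([1, 2, 3], c) for c in costs]
        kept = filter_by_cost(sols)
        # the retained set is exactly the low mode, by construction
        np.testing.assert_array_equal(kept, np.arange(12))
        thr = otsu_threshold(costs)
        assert thr == pytest.approx(_sweep_otsu_oracle(costs))
        assert lo.max() < thr < hi.min()

    def test_failed_runs_excluded(self):
        sols = [_fake_solution([1, 2], 1.0) for _ in range(3)]
        sols[1].failed = True
        assert 1 not in filter_by_cost(sols)

    def test_too_few_solutions_rejected(self):
        with pytest.raises(SelectionError):
            filter_by_cost([_fake_solution([1], 1.0)])


class TestClustering:
    def test_single_member_cluster_has_zero_distance(self):
        sols = [_fake_solution([1.0, 2.0], 1.0),
                _fake_solution([3.5, 4.0], 1.0)]
        rep = cluster_solutions(sols, retained=np.array([0, 1]))
        assert all(v == 0.0 for v in rep.d_C.values())

    def test_pair_distance_halved(self):
        # two members at Euclidean distance d: d_C = d / 2
        sols = [_fake_solution([1.0, 2.0], 1.0),
                _fake_solution([1.3, 2.0], 1.0)]
        rep = cluster_solutions(sols, retained=np.array([0, 1]), t_cut=1.0)
        d = np.linalg.norm(rep.peak_latencies[0] - rep.peak_latencies[1])
        assert rep.d_C[rep.winner] == pytest.approx(d / 2)

    def test_recurring_cluster_beats_scattered(self, rng):
        tight = [_fake_solution(list(2.0 + rng.normal(0, 0.02, 3)), 1.0)
                 for _ in range(8)]
        scattered = [_fake_solution([0.7, 3.9, 1.4], 1.0),
                     _fake_solution([4.2, 0.9, 3.1], 1.0)]
        sols = tight + scattered
        rep = cluster_solutions(sols, retained=np.arange(10))
        assert set(rep.winner_runs) == set(range(8))
        # brute-force check: the winner minimizes diameter / size among
        # the multi-member clusters of this cut
        for cid, d in rep.d_C.items():
            if rep.n_C[cid] >= 2:
                assert rep.d_C[rep.winner] <= d

    def test_larger_cluster_wins_ties(self):
        sols = ([_fake_solution([1.0, 1.0], 1.0)] * 3
                + [_fake_solution([3.0, 3.0], 1.0)] * 2)
        rep = cluster_solutions(sols, retained=np.arange(5))
        assert rep.n_C[rep.winner] == 3

    def test_degenerate_latencies_excluded(self):
        good = [_fake_solution([1.0, 2.0], 1.0),
                _fake_solution([1.05, 2.05], 1.0)]
        collapsed = [_fake_solution([0.02, 0.02], 1.0) for _ in range(3)]
        rep = cluster_solutions(good + collapsed, retained=np.arange(5))
        assert set(rep.winner_runs) == {0, 1}


class TestFinalize:
    def test_identical_members_average_to_member(self):
        sols = [_fake_solution([1.0, 2.0], 1.0) for _ in range(3)]
        avg = finalize_hrfs(np.array([0, 1, 2]), sols)
        np.testing.assert_allclose(avg, sols[0].hrf_taps)

    def test_two_members_give_midpoint_curve(self):
        a, b = _fake_solution([1.0, 2.0], 1.0), _fake_solution([1.4, 2.4], 1.0)
        avg = finalize_hrfs(np.array([0, 1]), [a, b])
        np.testing.assert_allclose(avg, (a.hrf_taps + b.hrf_taps) / 2)

    def test_winner_mean_pl_within_member_range(self, rng):
        sols = [_fake_solution(list(2.0 + rng.normal(0, 0.1, 2)), 1.0)
                for _ in range(6)]
        rep = cluster_solutions(sols, retained=np.arange(6), t_cut=2.0)
        member_pls = rep.peak_latencies
        for m in range(2):
            lo, hi = member_pls[:, m].min(), member_pls[:, m].max()
            mean_pl = np.argmax(rep.final_hrfs[m]) * 0.5
            assert lo - 0.5 <= mean_pl <= hi + 0.5


class TestPipelineProperties:
    def test_selection_idempotent_on_winner(self, rng):
        sols = [_fake_solution(list(2.0 + rng.normal(0, 0.05, 3)), 1.0)
                for _ in range(6)]
        rep1 = select_stable(sols)
        rep2 = select_stable([sols[i] for i in rep1.winner_runs])
        np.testing.assert_allclose(rep1.final_hrfs, rep2.final_hrfs)

    def test_injected_outlier_never_changes_winner(self, rng):
        sols = [_fake_solution(list(1.5 + rng.normal(0, 0.05, 3)), 1.0)
                for _ in range(8)]
        rep1 = select_stable(sols)
        outlier = _fake_solution([4.0, 0.3, 2.2], 10.0)
        rep2 = select_stable(sols + [outlier])
        assert set(rep2.winner_runs) == set(rep1.winner_runs)

    def test_lowest_cost_pick(self):
        sols = [_fake_solution([1.0], c) for c in (3.0, 1.0, 2.0)]
        assert lowest_cost_pick(sols) == 1
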