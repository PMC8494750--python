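"""Tests of the Q objective and the two-stage rate inference."""

import warnings

import numpy as np
import pytest

from cellcolony import (
    GridSpec,
    KCurve,
    SimulationParams,
    fit_T,
    fit_lambda_tau,
    model_k20_vs_N,
    model_k_at_N0,
    q_deviation,
)
from cellcolony.inference import _cell_seed, _final_pattern, _scan_grid
from cellcolony.spatial_stats import DEFAULT_R_GRID, ripley_k


def _curve(values, r=None):
    r = DEFAULT_R_GRID if r is None else np.asarray(r, dtype=float)
    vals = np.asarray(values, dtype=float)
    return KCurve(r, vals * r ** 2, N=98, area=1e6)


class TestQDeviation:
    def test_identical_curves_give_zero(self):
        c = _curve(np.linspace(4, 3.2, DEFAULT_R_GRID.size))
        assert q_deviation(c, c) == 0.0

    def test_constant_offset_sums_squares(self):
        a = _curve(np.full(DEFAULT_R_GRID.size, 4.0))
        b = _curve(np.full(DEFAULT_R_GRID.size, 5.0))
        assert q_deviation(a, b) == pytest.approx(18.0)
        assert q_deviation(b, a) == pytest.approx(18.0)  # symmetric

    def test_three_point_hand_computed(self):
        r = [10.0, 20.0, 30.0]
        a = _curve([4.0, 3.5, 3.2], r)
        b = _curve([3.5, 4.7, 1.2], r)
        # 0.5^2 + 1.2^2 + 2.0^2 = 5.69
        assert q_deviation(a, b) == pytest.approx(5.69)

    def test_mismatched_grids_rejected(self):
        a = _curve([4.0, 3.5], [10.0, 20.0])
        b = _curve([4.0, 3.5], [10.0, 25.0])
        with pytest.raises(ValueError):
            q_deviation(a, b)


class TestModelCurve:
    def test_single_run_equals_direct_simulation(self):
        p = SimulationParams(lam=0.5)
        curve = model_k_at_N0(p, n_runs=1, base_seed=21)
        child = _cell_seed(21).spawn(1)[0]
        pat = _final_pattern(p.with_(adhesion_mode="constant"),
                             np.random.default_rng(child))
        direct = ripley_k(pat, DEFAULT_R_GRID, edge_correction="periodic")
        assert np.array_equal(curve.K, direct.K)

    def test_free_cells_approach_poisson_as_division_slows(self):
        # tau0 = 1: motility never reduced.  Slower division leaves more
        # time for diffusion to erase birth correlations, so K/r^2 at N0
        # approaches pi monotonically from above; a residual excess always
        # remains because domain-scale mixing takes ~L^2/4D >> 24 h
        devs = []
        for lam in (0.15, 0.05, 0.02):
            c = model_k_at_N0(SimulationParams(tau0=1.0, lam=lam),
                              n_runs=30, base_seed=4)
            kr2 = c.K / c.r ** 2
            assert (kr2 > np.pi - 3 * c.se).all()  # excess, never depletion
            devs.append(np.abs(kr2 - np.pi).max())
        assert devs[0] > devs[1] > devs[2]
        assert devs[2] < 0.8  # far below the adhesive colony's ~5 excess

    def test_fast_single_radius_k_equals_ripley_estimator(self):
        # the growth scans count pairs with a KD-tree; must equal the full
        # Ripley estimator at that radius
        from cellcolony.inference import _k_single_r_periodic
        from cellcolony.spatial_stats import PointPattern
        rng = np.random.default_rng(31)
        pts = rng.random((250, 2)) * 1000
        fast = _k_single_r_periodic(pts, 1000.0, 20.0)
        full = ripley_k(PointPattern(pts, (0, 0, 1000, 1000)), [20.0],
                        edge_correction="periodic").K[0] / 400.0
        assert fast == pytest.approx(full, rel=1e-12)

    def test_replicate_se_shrinks_with_n_runs(self):
        p = SimulationParams(lam=0.5)
        c20 = model_k_at_N0(p, n_runs=20, base_seed=9)
        c80 = model_k_at_N0(p, n_runs=80, base_seed=9)
        assert c80.se.mean() < c20.se.mean()


class TestFitLambdaTau:
    def test_single_cell_grid_returns_that_cell(self):
        p = SimulationParams()
        ref = model_k_at_N0(p.with_(lam=0.4, tau0=0.6), n_runs=3, base_seed=2)
        grid = GridSpec(lam_values=[0.4], tau_values=[0.6], n_runs=3,
                        n_runs_final=3, refine=False, base_seed=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            surf = fit_lambda_tau(ref, grid, p)
        assert surf.argmin == (0.4, 0.6)
        assert surf.Q[0, 0] == 0.0  # same seeds, same model: exact match

    def test_grid_evaluation_is_order_invariant(self):
        p = SimulationParams()
        ref = model_k_at_N0(p, n_runs=3, base_seed=30)
        single = _scan_grid([0.5], [0.8], ref, p, 3, base_seed=7)[0, 0]
        joint = _scan_grid([0.3, 0.5], [0.6, 0.8], ref, p, 3, base_seed=7)
        assert joint[1, 1] == single

    def test_poisson_reference_prefers_high_motility(self):
        # a CSR reference (K/r^2 = pi) is best matched by tau near/above 1
        p = SimulationParams()
        ref = _curve(np.full(DEFAULT_R_GRID.size, np.pi))
        Q = _scan_grid([0.3], [0.2, 0.6, 1.0, 1.4], ref, p, 8, base_seed=6)[0]
        assert Q.argmin() >= 2  # tau >= 1.0
        assert Q[0] > Q[2]  # strongly adhesive colonies are clearly worse

    def test_boundary_argmin_warns(self):
        p = SimulationParams()
        ref = _curve(np.full(DEFAULT_R_GRID.size, np.pi))
        grid = GridSpec(lam_values=[0.3, 0.35], tau_values=[0.1, 0.15],
                        n_runs=2, n_runs_final=2, refine=False, base_seed=0)
        with pytest.warns(UserWarning, match="boundary"):
            fit_lambda_tau(ref, grid, p)


class TestQVariance:
    def test_more_runs_reduce_q_variance_at_fixed_cell(self):
        # replicate variance of Q itself shrinks with the per-cell run count
        p = SimulationParams(N0=60, lam=0.4)
        ref = model_k_at_N0(p, n_runs=100, base_seed=999)
        for lam, tau in [(0.3, 0.4), (0.5, 0.8), (0.8, 1.2)]:
            cell = p.with_(lam=lam, tau0=tau)
            qs = {n: [q_deviation(model_k_at_N0(cell, n_runs=n, base_seed=b), ref)
                      for b in range(100, 105)]
                  for n in (20, 80)}
            assert np.var(qs[80]) < np.var(qs[20])


class TestFitT:
    def _short_params(self):
        # small threshold and brisk division keep these runs cheap
        return SimulationParams(lam=0.4, tau0=0.5, N0=60, T=1.8e-3)

    def test_T_zero_candidate_reproduces_constant_tau_exactly(self):
        p = self._short_params()
        ref = model_k20_vs_N(p.with_(T=0.0), n_runs=3, base_seed=11, t_end=4.0)
        T_hat, scan = fit_T(ref, t_candidates=[0.0, 5e-3], params_base=p,
                            n_runs=3, base_seed=11, t_end=4.0)
        dev = dict(scan)
        assert dev[0.0] == 0.0  # common random numbers: exact reproduction
        assert T_hat == 0.0

    def test_csr_like_reference_pushes_T_to_fastest_relaxation(self):
        # reference flat at pi for all N favours the largest T candidate
        p = self._short_params()
        ref = [(n, np.pi) for n in range(60, 240, 10)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            T_hat, scan = fit_T(ref, t_candidates=[0.0, 5e-3, 8e-2],
                                params_base=p, n_runs=4, base_seed=13,
                                t_end=6.0)
        devs = dict(scan)
        assert T_hat == 8e-2
        assert devs[8e-2] < devs[5e-3] < devs[0.0]

    def test_reference_without_dense_samples_rejected(self):
        p = self._short_params()
        with pytest.raises(ValueError):
            fit_T([(10, 3.5)], t_candidates=[0.0], params_base=p, n_runs=1)
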