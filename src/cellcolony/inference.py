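"""Simulation-based inference of the colony model's rates.

Stage 1 recovers the division rate lambda and the low-density adhesion factor
tau0 by a grid search: for each (lambda, tau) pair the constant-adhesion model
is run repeatedly from 50 cells until the population reaches N0, the average
K(r)/r^2 of the final patterns is formed, and the quadratic deviation

    Q = sum_r (K_mod(r)/r^2 - K_ref(r)/r^2)^2

to the reference curve is minimised over the grid (coarse pass plus a local
refinement).  Stage 2 freezes (lambda, tau0) and scans the density-dependence
rate T of the tau(N) law against the K(20 um)/r^2 vs N curve, scoring a
binned least-squares deviation.  Both stages use common random numbers: the
replicate seeds derive from the base seed and the run index only, so every
grid cell (or T candidate) replays the same noise realisations.  That cancels
most replicate noise out of Q differences between cells, makes the fit
independent of grid evaluation order, and lets the T = 0 candidate reproduce
the constant-adhesion curves exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .simulator import SimulationParams, run_until
from .spatial_stats import DEFAULT_R_GRID, KCurve, PointPattern, bin_by_N, k_at_r, ripley_k

__all__ = [
    "GridSpec",
    "QSurface",
    "InferenceResult",
    "q_deviation",
    "model_k_at_N0",
    "fit_lambda_tau",
    "model_k20_vs_N",
    "fit_T",
    "default_t_candidates",
]

R_STAR = 20.0  # analysis scale (um) for the K/r^2 vs N curve


@dataclass
class GridSpec:
    """Stage-1 search grid over (lambda, tau)."""

    lam_values: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(0.15, 1.0 + 1e-9, 0.05), 4))
    tau_values: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(0.0, 1.5 + 1e-9, 0.05), 4))
    n_runs: int = 50            # screening pass, every grid cell
    n_runs_final: int = 200     # candidate re-evaluation and refinement
    rescan_margin: float = 1.0  # Q margin above the screen minimum to keep
    max_rescan: int = 40        # cap on re-evaluated cells
    base_seed: int = 0
    refine: bool = True
    refine_step: float = 0.01
    refine_span: float = 0.02

    def __post_init__(self):
        self.lam_values = np.asarray(self.lam_values, dtype=float)
        self.tau_values = np.asarray(self.tau_values, dtype=float)
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if (self.lam_values <= 0).any() or (self.tau_values < 0).any():
            raise ValueError("lambda values must be positive, tau values non-negative")


@dataclass
class QSurface:
    """Q over a (lambda, tau) grid with its minimiser."""

    lam_values: np.ndarray
    tau_values: np.ndarray
    Q: np.ndarray  # shape (len(lam_values), len(tau_values))
    argmin: tuple  # (lam_hat, tau0_hat)
    n_runs: int
    refined: "QSurface | None" = None
    rescanned: dict = field(default_factory=dict)  # {(lam, tau): Q at n_runs_final}

    @property
    def lam_hat(self) -> float:
        return self.argmin[0]

    @property
    def tau0_hat(self) -> float:
        return self.argmin[1]


@dataclass
class InferenceResult:
    """Outcome of the two-stage fit."""

    lam_hat: float
    tau0_hat: float
    T_hat: float
    q_surface: QSurface
    t_scan: list  # [(T, deviation), ...]
    base_seed: int
    n_runs_stage1: int
    n_runs_stage2: int


def q_deviation(k_model: KCurve, k_ref: KCurve) -> float:
    """Quadratic deviation between two K/r^2 curves on a shared r grid."""
    if k_model.r.shape != k_ref.r.shape or not np.allclose(k_model.r, k_ref.r):
        raise ValueError("curves must share the same r grid")
    diff = k_model.K / k_model.r ** 2 - k_ref.K / k_ref.r ** 2
    return float((diff ** 2).sum())


def _cell_seed(base_seed: int) -> np.random.SeedSequence:
    # common random numbers: every (lam, tau) grid cell replays the same
    # replicate seeds, which cancels most replicate noise out of Q
    # *differences* between cells and keeps the fit independent of the
    # order in which cells are evaluated
    return np.random.SeedSequence(int(base_seed))


def _final_pattern(params: SimulationParams, rng) -> PointPattern:
    traj = run_until(params, N_target=params.N0, rng=rng)
    return PointPattern(traj.final.positions, (0.0, 0.0, params.L, params.L))


def model_k_at_N0(params: SimulationParams, n_runs: int, r_grid=None,
                  base_seed: int = 0, seed_seq: np.random.SeedSequence | None = None
                  ) -> KCurve:
    """Average K(r) over ``n_runs`` independent runs stopped at N = N0.

    Constant-adhesion mode; each run starts from ``N_init`` uniform cells.
    The returned curve carries the replicate SE of K/r^2 in ``se``.
    """
    r_grid = DEFAULT_R_GRID if r_grid is None else np.asarray(r_grid, dtype=float)
    params = params.with_(adhesion_mode="constant")
    if seed_seq is None:
        seed_seq = _cell_seed(base_seed)
    curves = np.empty((n_runs, r_grid.size))
    n_final = np.empty(n_runs)
    for k, child in enumerate(seed_seq.spawn(n_runs)):
        pat = _final_pattern(params, np.random.default_rng(child))
        curves[k] = ripley_k(pat, r_grid, edge_correction="periodic").K
        n_final[k] = pat.N
    K_mean = curves.mean(axis=0)
    se = (curves / r_grid ** 2).std(axis=0, ddof=1) / np.sqrt(n_runs) if n_runs > 1 else None
    return KCurve(r_grid, K_mean, N=float(n_final.mean()), area=params.L ** 2,
                  edge_correction="periodic", se=se)


def _scan_grid(lam_values, tau_values, k_ref, params_base, n_runs, base_seed):
    Q = np.empty((len(lam_values), len(tau_values)))
    for i, lam in enumerate(lam_values):
        for j, tau in enumerate(tau_values):
            p = params_base.with_(lam=float(lam), tau0=float(tau),
                                  adhesion_mode="constant")
            k_mod = model_k_at_N0(p, n_runs, r_grid=k_ref.r,
                                  seed_seq=_cell_seed(base_seed))
            Q[i, j] = q_deviation(k_mod, k_ref)
    return Q


def _argmin_low(lam_values, tau_values, Q):
    # ties broken toward smaller lambda, then smaller tau: first strict min
    # in lam-major order
    flat = np.argmin(Q)  # np.argmin returns the first occurrence (row-major)
    i, j = np.unravel_index(flat, Q.shape)
    return float(lam_values[i]), float(tau_values[j]), i, j


def fit_lambda_tau(k_ref: KCurve, grid: GridSpec,
                   params_base: SimulationParams) -> QSurface:
    """Stage-1 grid search for (lambda, tau0) minimising Q against ``k_ref``.

    Three passes, all with common random numbers: (1) a screen of the full
    coarse grid at ``grid.n_runs`` replicates; (2) re-evaluation of every
    cell whose screened Q lies within ``grid.rescan_margin`` of the screen
    minimum at ``grid.n_runs_final`` replicates — a one-coarse-step move
    along the Q valley changes Q by less than the screening noise floor, so
    the near-minimal cells must be re-ranked at full replication before the
    minimiser is trusted; (3) if ``grid.refine``, a local pass at
    ``grid.refine_step`` spanning ``grid.refine_span`` around the winner,
    again at full replication.  Warns when the final argmin sits on the
    boundary of the search region.
    """
    Q = _scan_grid(grid.lam_values, grid.tau_values, k_ref, params_base,
                   grid.n_runs, grid.base_seed)
    lam_hat, tau_hat, i, j = _argmin_low(grid.lam_values, grid.tau_values, Q)
    surface = QSurface(grid.lam_values, grid.tau_values, Q,
                       (lam_hat, tau_hat), grid.n_runs)

    if grid.n_runs_final > grid.n_runs:
        flat = np.argsort(Q, axis=None)
        keep = [np.unravel_index(f, Q.shape) for f in flat[:grid.max_rescan]
                if Q[np.unravel_index(f, Q.shape)] <= Q.min() + grid.rescan_margin]
        q_best = np.inf
        for (ii, jj) in keep:
            lam, tau = grid.lam_values[ii], grid.tau_values[jj]
            p = params_base.with_(lam=float(lam), tau0=float(tau),
                                  adhesion_mode="constant")
            k_mod = model_k_at_N0(p, grid.n_runs_final, r_grid=k_ref.r,
                                  seed_seq=_cell_seed(grid.base_seed))
            q = q_deviation(k_mod, k_ref)
            surface.rescanned[(float(lam), float(tau))] = q
            # strict '<' keeps the earlier (lower-Q-screened) cell on ties
            if q < q_best:
                q_best = q
                lam_hat, tau_hat = float(lam), float(tau)
        surface.argmin = (lam_hat, tau_hat)

    if grid.refine:
        lam_fine = np.round(np.arange(lam_hat - grid.refine_span,
                                      lam_hat + grid.refine_span + 1e-9,
                                      grid.refine_step), 4)
        tau_fine = np.round(np.arange(tau_hat - grid.refine_span,
                                      tau_hat + grid.refine_span + 1e-9,
                                      grid.refine_step), 4)
        lam_fine = lam_fine[(lam_fine >= grid.lam_values[0] - 1e-9)
                            & (lam_fine <= grid.lam_values[-1] + 1e-9)]
        tau_fine = tau_fine[(tau_fine >= grid.tau_values[0] - 1e-9)
                            & (tau_fine <= grid.tau_values[-1] + 1e-9)]
        Qf = _scan_grid(lam_fine, tau_fine, k_ref, params_base,
                        grid.n_runs_final, grid.base_seed)
        lam_hat, tau_hat, _, _ = _argmin_low(lam_fine, tau_fine, Qf)
        surface.refined = QSurface(lam_fine, tau_fine, Qf,
                                   (lam_hat, tau_hat), grid.n_runs_final)
        surface.argmin = (lam_hat, tau_hat)
    if (np.isclose(lam_hat, grid.lam_values[0]) or np.isclose(lam_hat, grid.lam_values[-1])
            or np.isclose(tau_hat, grid.tau_values[0])
            or np.isclose(tau_hat, grid.tau_values[-1])):
        warnings.warn("Q minimum lies on the boundary of the search grid")
    return surface


def default_t_candidates() -> np.ndarray:
    """{0} plus 12 log-spaced values in [1e-4, 1e-1]."""
    return np.concatenate([[0.0], np.logspace(-4, -1, 12)])


def model_k20_vs_N(params: SimulationParams, n_runs: int, base_seed: int = 0,
                   N_max: int | None = None, t_end: float = 24.0,
                   sample_every: float = 0.5, r_star: float = R_STAR):
    """Samples of (N, K(r*)/r*^2) along density-dependent growth runs.

    Each run starts at ``N_init``, stops at ``N_max`` (default 6*N0) or
    ``t_end`` hours, whichever first, and is sampled every ``sample_every``
    hours.  Run seeds depend only on (base_seed, run index): scanning T with
    the same base seed yields common random numbers across candidates.
    """
    if N_max is None:
        N_max = 6 * params.N0
    times = np.arange(0.0, t_end + 1e-9, sample_every)
    samples = []
    children = np.random.SeedSequence(int(base_seed)).spawn(n_runs)
    for child in children:
        traj = run_until(params, N_target=N_max, t_end=t_end,
                         sample_times=times, rng=np.random.default_rng(child))
        for snap in traj.snapshots:
            if snap.N < 2:
                continue
            samples.append((snap.N,
                            _k_single_r_periodic(snap.positions, params.L, r_star)))
    return samples


def _k_single_r_periodic(pts: np.ndarray, L: float, r: float) -> float:
    """K(r)/r^2 with periodic minimum-image distances via a KD-tree pair
    count; equals ripley_k(..., 'periodic') at a single radius but O(N log N)
    for the dense snapshots of the growth scans."""
    n = len(pts)
    tree = cKDTree(pts, boxsize=L)
    pairs = tree.count_neighbors(tree, r)  # ordered pairs incl. self-pairs
    return float(L * L / (n * (n - 1)) * (pairs - n) / r ** 2)


def fit_T(k20_vs_N_ref, t_candidates=None, params_base: SimulationParams = None,
          n_runs: int = 1000, base_seed: int = 0, n_bins: int = 8,
          t_end: float = 24.0):
    """Stage-2 scan of the density-dependence rate T.

    ``k20_vs_N_ref`` is a sequence of (N, K(20)/r^2) reference samples.
    Samples with N < N0 are discarded (tau(N) is tau0 there regardless of T);
    the survivors define ``n_bins`` equal-width N bins.  For each candidate T
    the density-dependent model is run with the frozen (lambda, tau0), its
    samples are binned on the same edges, and the summed squared difference
    of bin means (over bins populated on both sides) is the score.  Returns
    ``(T_hat, scan)`` with ``scan`` a list of (T, deviation).
    """
    if params_base is None:
        raise ValueError("params_base with fitted lam and tau0 is required")
    t_candidates = default_t_candidates() if t_candidates is None else np.asarray(
        t_candidates, dtype=float)
    ref = np.asarray(list(k20_vs_N_ref), dtype=float)
    ref = ref[ref[:, 0] >= params_base.N0]
    if len(ref) == 0:
        raise ValueError("reference has no samples with N >= N0")
    edges = np.linspace(ref[:, 0].min(), max(ref[:, 0].max(), ref[:, 0].min() + 1),
                        n_bins + 1)
    ref_binned = bin_by_N(ref, edges=edges).set_index("N_center")

    scan = []
    for T in t_candidates:
        p = params_base.with_(T=float(T), adhesion_mode="density_dependent")
        samples = np.asarray(model_k20_vs_N(p, n_runs, base_seed=base_seed,
                                            t_end=t_end), dtype=float)
        samples = samples[samples[:, 0] >= params_base.N0]
        if len(samples) == 0:
            scan.append((float(T), np.inf))
            continue
        mod_binned = bin_by_N(samples, edges=edges).set_index("N_center")
        common = ref_binned.index.intersection(mod_binned.index)
        dev = float(((mod_binned.loc[common, "mean"]
                      - ref_binned.loc[common, "mean"]) ** 2).sum())
        scan.append((float(T), dev))
    devs = [d for _, d in scan]
    T_hat = float(scan[int(np.argmin(devs))][0])
    if T_hat in (t_candidates[0], t_candidates[-1]) and len(t_candidates) > 1:
        warnings.warn("optimal T lies on the boundary of the scan")
    return T_hat, scan
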