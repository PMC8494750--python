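"""Off-lattice stochastic model of a proliferating cell colony on a substrate.

Each cell is a point particle of interaction radius ``r0`` performing Brownian
motion with diffusivity ``tau * D``.  A cell in contact with another cell
(centre distance strictly below ``2*r0``) has its motility reduced by the
dimensionless adhesion factor ``tau``; an isolated cell moves with ``tau = 1``.
Cells divide at rate ``lam``: the offspring is proposed at distance exactly
``2*r0`` from the parent at a uniformly random angle and is accepted only if
it does not overlap (centre distance < ``2*r0``) any existing cell.  The
adhesion factor can optionally depend on the population size ``N`` through an
exponential relaxation toward 1 above a threshold ``N0``
(:func:`tau_of_N`), modelling the loss of contact inhibition as the colony
becomes dense.

Two engines integrate the same dynamics: pure-numpy step functions
(:func:`step_motion`, :func:`attempt_divisions`) and a fused numba kernel
used by :func:`run_until`.  Both consume an identical ``numpy.random.Generator``
stream, so trajectories agree bit-for-bit for a given seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from . import _kernels

__all__ = [
    "SimulationParams",
    "Population",
    "Trajectory",
    "SimulationStallError",
    "tau_of_N",
    "neighbor_flags",
    "step_motion",
    "attempt_divisions",
    "run_until",
]

BOUNDARIES = ("periodic", "reflecting")
# strict '<' comparisons against (2*r0)^2 use a relative tie guard so that
# pairs at distance exactly 2*r0 (parent/offspring at birth) do not flip on
# floating-point rounding noise
_TIE_GUARD = 1.0 - 1e-12
ADHESION_MODES = ("constant", "density_dependent")


class SimulationStallError(RuntimeError):
    """Raised when a target population size is not reached within the step cap."""


@dataclass(frozen=True)
class SimulationParams:
    """All constants of the colony model.

    Units: lengths in micrometres, times in hours.  ``lam * dt`` must not
    exceed 1 because division is a per-step Bernoulli trial.
    """

    r0: float = 10.0            # particle interaction radius (um)
    D: float = 500.0            # free diffusion coefficient (um^2/h)
    tau0: float = 0.52          # adhesion factor at low density
    lam: float = 0.2            # division rate (1/h)
    T: float = 1.8e-3           # density-dependence rate of tau (1/cells)
    N0: int = 98                # population threshold of the tau(N) law
    dt: float = 0.01            # time step (h)
    L: float = 1000.0           # square substrate side (um)
    boundary: str = "periodic"
    N_init: int = 50
    adhesion_mode: str = "density_dependent"
    seed: int | None = None

    def __post_init__(self):
        if self.r0 <= 0:
            raise ValueError("r0 must be positive")
        if self.D < 0:
            raise ValueError("D must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.L <= 4 * self.r0:
            raise ValueError("domain side L must exceed 4*r0")
        if self.lam < 0 or self.lam * self.dt > 1:
            raise ValueError("need 0 <= lam*dt <= 1 (per-step Bernoulli division)")
        if self.tau0 < 0:
            raise ValueError("tau0 must be non-negative")
        if self.T < 0:
            raise ValueError("T must be non-negative")
        if self.N0 < 1 or self.N_init < 1:
            raise ValueError("N0 and N_init must be >= 1")
        if self.boundary not in BOUNDARIES:
            raise ValueError(f"boundary must be one of {BOUNDARIES}")
        if self.adhesion_mode not in ADHESION_MODES:
            raise ValueError(f"adhesion_mode must be one of {ADHESION_MODES}")

    def with_(self, **kwargs) -> "SimulationParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class Population:
    """Colony state: cell positions (um), elapsed time (h)."""

    positions: np.ndarray
    t: float = 0.0

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)

    @property
    def N(self) -> int:
        return self.positions.shape[0]


@dataclass
class Trajectory:
    """Snapshots of a run plus division bookkeeping."""

    snapshots: list
    params: SimulationParams
    n_steps: int = 0
    division_attempts: int = 0
    division_rejections: int = 0

    @property
    def final(self) -> Population:
        return self.snapshots[-1]

    @property
    def rejection_fraction(self) -> float:
        if self.division_attempts == 0:
            return 0.0
        return self.division_rejections / self.division_attempts


def tau_of_N(N, params: SimulationParams):
    """Adhesion factor as a function of the population size.

    Constant mode returns ``tau0`` for any ``N``.  Density-dependent mode
    returns ``tau0`` below ``N0`` and ``1 - (1 - tau0) * exp(-T * (N - N0))``
    at or above it, which is exactly continuous at ``N0`` and approaches 1 as
    the colony grows.  Accepts scalars or arrays.
    """
    N = np.asarray(N)
    if np.any(N < 1):
        raise ValueError("N must be >= 1")
    if params.adhesion_mode == "constant":
        out = np.full(N.shape, params.tau0)
    else:
        # the formula equals tau0 at N = N0; branch on N <= N0 so the
        # continuity there is exact in floating point as well
        out = np.where(
            N <= params.N0,
            params.tau0,
            1.0 - (1.0 - params.tau0) * np.exp(-params.T * np.maximum(N - params.N0, 0)),
        )
    return float(out) if out.ndim == 0 else out


def _pairwise_deltas(positions: np.ndarray, params: SimulationParams):
    d = positions[None, :, :] - positions[:, None, :]
    if params.boundary == "periodic":
        d -= params.L * np.round(d / params.L)
    return d


def neighbor_flags(pop: Population, params: SimulationParams) -> np.ndarray:
    """Boolean per cell: True iff some other cell lies strictly within 2*r0.

    Ties at exactly 2*r0 count as non-contact.  Periodic domains use
    minimum-image distances.
    """
    n = pop.N
    if n == 1:
        return np.zeros(1, dtype=bool)
    d = _pairwise_deltas(pop.positions, params)
    d2 = (d ** 2).sum(axis=-1)
    np.fill_diagonal(d2, np.inf)
    return (d2 < (2 * params.r0) ** 2 * _TIE_GUARD).any(axis=1)


def _wrap(coords: np.ndarray, params: SimulationParams) -> np.ndarray:
    if params.boundary == "periodic":
        return coords % params.L
    folded = coords % (2.0 * params.L)
    return np.where(folded > params.L, 2.0 * params.L - folded, folded)


def step_motion(pop: Population, params: SimulationParams, rng: np.random.Generator) -> Population:
    """One Brownian step: x -> x + sqrt(2*tau_i*D*dt) * xi, xi ~ N(0, 1).

    ``tau_i`` is :func:`tau_of_N` of the current N for cells in contact and 1
    for isolated cells.  N and t bookkeeping: N unchanged, t advances by dt.
    """
    n = pop.N
    tau = tau_of_N(n, params)
    if tau < 0:
        raise ValueError("adhesion factor tau must be non-negative")
    flags = neighbor_flags(pop, params)
    sig = np.where(flags, math.sqrt(2.0 * tau * params.D * params.dt),
                   math.sqrt(2.0 * params.D * params.dt))
    xi = rng.standard_normal(2 * n)
    new = pop.positions.copy()
    new[:, 0] = _wrap(pop.positions[:, 0] + sig * xi[0::2], params)
    new[:, 1] = _wrap(pop.positions[:, 1] + sig * xi[1::2], params)
    return Population(new, pop.t + params.dt)


def attempt_divisions(pop: Population, params: SimulationParams,
                      rng: np.random.Generator) -> Population:
    """Per-cell Bernoulli division trials with non-overlap rejection.

    Each pre-existing cell attempts division with probability ``lam * dt``.
    The offspring site is at distance exactly ``2*r0`` from the parent at a
    uniform random angle; it is accepted iff its centre distance to every
    existing cell and every offspring already accepted this step is >= 2*r0.
    One proposal per attempt, no retry.  Existing cells never move here.
    """
    n = pop.N
    two_r0 = 2.0 * params.r0
    u = rng.random(n)
    positions = pop.positions
    accepted = list(positions)
    for i in range(n):
        if u[i] < params.lam * params.dt:
            ang = rng.random() * (2.0 * np.pi)
            site = np.array([positions[i, 0] + two_r0 * np.cos(ang),
                             positions[i, 1] + two_r0 * np.sin(ang)])
            site = _wrap(site, params)
            d = np.asarray(accepted) - site
            if params.boundary == "periodic":
                d -= params.L * np.round(d / params.L)
            d2 = (d ** 2).sum(axis=1)
            # the parent is at distance exactly 2*r0 by construction: a tie
            # is non-overlap, so skip it instead of testing a floating-point
            # knife edge
            d2[i] = np.inf
            if (d2 >= two_r0 ** 2 * _TIE_GUARD).all():
                accepted.append(site)
    return Population(np.asarray(accepted), pop.t)


def _init_positions(params: SimulationParams, rng: np.random.Generator) -> np.ndarray:
    return rng.random((params.N_init, 2)) * params.L


def run_until(params: SimulationParams,
              N_target: int | None = None,
              t_end: float | None = None,
              sample_times: Sequence[float] | None = None,
              max_steps: int = 2_000_000,
              rng: np.random.Generator | None = None,
              initial: Population | None = None,
              engine: str = "fast") -> Trajectory:
    """Run the colony from a uniform random start until a stop condition.

    Stops at the first step where ``N >= N_target`` or ``t >= t_end``
    (whichever is given; both may be).  Snapshots are recorded at the
    requested ``sample_times`` (simulation hours) and the final state is
    always appended.  ``engine='reference'`` integrates with the pure-numpy
    step functions; ``engine='fast'`` uses the fused numba kernel.  Both give
    bit-identical trajectories for the same seed.

    Raises :class:`SimulationStallError` if ``N_target`` is set, ``t_end`` is
    not, and the target is unreached after ``max_steps`` steps (division can
    stall at high density).
    """
    if N_target is None and t_end is None:
        raise ValueError("provide N_target and/or t_end")
    if N_target is not None and params.lam == 0 and N_target > params.N_init and initial is None:
        raise ValueError("N_target unreachable with lam = 0")
    if rng is None:
        rng = np.random.default_rng(params.seed)

    if initial is None:
        pop = Population(_init_positions(params, rng), 0.0)
    else:
        pop = Population(initial.positions.copy(), initial.t)
    target = int(N_target) if N_target is not None else np.iinfo(np.int64).max

    sample_steps = []
    if sample_times is not None:
        start = int(round(pop.t / params.dt))
        sample_steps = sorted({int(round(ts / params.dt)) - start
                               for ts in sample_times if ts >= pop.t - 1e-12})
    end_step = max_steps
    if t_end is not None:
        end_step = min(end_step, max(0, int(math.ceil((t_end - pop.t) / params.dt - 1e-9))))

    snapshots: list[Population] = []
    step = 0
    attempts = rejections = 0

    def _snap():
        snapshots.append(Population(pop.positions.copy(), pop.t))

    if sample_steps and sample_steps[0] == 0:
        _snap()
        sample_steps.pop(0)

    if engine == "reference":
        # division bookkeeping is reported by the fast engine only
        while step < end_step and pop.N < target:
            pop = step_motion(pop, params, rng)
            pop = attempt_divisions(pop, params, rng)
            step += 1
            if sample_steps and step == sample_steps[0]:
                _snap()
                sample_steps.pop(0)
    elif engine == "fast":
        counters = np.zeros(3, dtype=np.int64)
        cap = max(4 * pop.N + 64, 2 * (target if N_target is not None else 0) + 64)
        buf = np.empty((cap, 2), dtype=float)
        buf[:pop.N] = pop.positions
        n = pop.N
        t0 = pop.t
        while step < end_step and n < target:
            seg = end_step - step
            if sample_steps:
                seg = min(seg, sample_steps[0] - step)
            n, status = _kernels.run_segment(
                buf, n, params.lam, params.dt, params.D, params.tau0, params.T,
                params.N0, params.r0, params.L,
                params.adhesion_mode == "density_dependent",
                params.boundary == "periodic",
                target, seg, rng, counters)
            step = int(counters[0])
            pop = Population(buf[:n].copy(), t0 + step * params.dt)
            if status == _kernels.DONE_FULL:
                cap *= 2
                new_buf = np.empty((cap, 2), dtype=float)
                new_buf[:n] = buf[:n]
                buf = new_buf
                continue
            if sample_steps and step == sample_steps[0]:
                _snap()
                sample_steps.pop(0)
        attempts = int(counters[1])
        rejections = int(counters[2])
    else:
        raise ValueError("engine must be 'fast' or 'reference'")

    if (N_target is not None and t_end is None and pop.N < target):
        raise SimulationStallError(
            f"N = {pop.N} < N_target = {target} after {step} steps")

    if not snapshots or snapshots[-1].t != pop.t or snapshots[-1].N != pop.N:
        _snap()
    return Trajectory(snapshots, params, n_steps=step,
                      division_attempts=attempts, division_rejections=rejections)
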