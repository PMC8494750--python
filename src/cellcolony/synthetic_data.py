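"""Synthetic "experiments": time-sampled nucleus point patterns with known truth.

Emulates the in vitro setup: wells seeded with 10^4 cells over 1.93 cm^2 give
about 50 cells per 10^-2 cm^2 image at the first (2 h) observation, colonies
are then imaged at {2, 4, 6, 8, 12, 24} h, and centroid detection introduces
small localisation jitter and occasional misses.  Simulation time 0
corresponds to the 2 h experimental time point (cell deposition is assumed
complete by then), so an experimental time t maps to simulation time t - 2 h.

Every dataset is reproducible bit-for-bit from its spec (truth parameters +
seed), which is what makes the downstream statistics and inference testable
without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .simulator import SimulationParams, run_until
from .spatial_stats import PointPattern

__all__ = [
    "SyntheticExperimentSpec",
    "SyntheticDataset",
    "generate_experiment",
    "generate_poisson_null",
    "expected_initial_count",
    "DEPOSITION_LAG_H",
]

DEPOSITION_LAG_H = 2.0  # experimental hours elapsed before simulation t = 0


@dataclass
class SyntheticExperimentSpec:
    """Ground truth plus acquisition-noise settings for one synthetic assay."""

    truth: SimulationParams = field(default_factory=SimulationParams)
    sample_times: tuple = (2.0, 4.0, 6.0, 8.0, 12.0, 24.0)  # experimental hours
    n_images: int = 10
    jitter_sigma: float = 1.0   # centroid localisation noise (um)
    miss_rate: float = 0.02     # probability a cell goes undetected
    render_images: bool = False
    seed: int = 0

    def __post_init__(self):
        st = tuple(float(t) for t in self.sample_times)
        if any(t < DEPOSITION_LAG_H for t in st):
            raise ValueError(f"sample times start at deposition + {DEPOSITION_LAG_H} h")
        if list(st) != sorted(st):
            raise ValueError("sample_times must be increasing")
        if not (0 <= self.miss_rate < 1):
            raise ValueError("miss_rate must be in [0, 1)")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be non-negative")
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        self.sample_times = st


@dataclass
class SyntheticDataset:
    """Patterns with time/replicate metadata plus the generating truth."""

    patterns: list
    spec: SyntheticExperimentSpec
    micrographs: list | None = None

    @property
    def manifest(self) -> dict:
        m = asdict(self.spec)
        m["truth"] = asdict(self.spec.truth)
        m["n_patterns"] = len(self.patterns)
        return m


def _apply_detection_noise(points: np.ndarray, L: float, jitter: float,
                           miss: float, rng: np.random.Generator) -> np.ndarray:
    pts = points.copy()
    if jitter > 0:
        pts = (pts + rng.normal(0.0, jitter, pts.shape)) % L
    if miss > 0:
        pts = pts[rng.random(len(pts)) >= miss]
    return pts


def generate_experiment(spec: SyntheticExperimentSpec) -> SyntheticDataset:
    """Simulate ``n_images`` replicate fields and corrupt them like a detector.

    Each replicate runs the truth model, is snapshotted at the experimental
    sample times, then each centroid gets iid Gaussian jitter and is dropped
    independently with ``miss_rate``.  With ``render_images`` the noisy
    patterns are additionally rendered to micrographs.
    """
    truth = spec.truth
    window = (0.0, 0.0, truth.L, truth.L)
    sim_times = [t - DEPOSITION_LAG_H for t in spec.sample_times]
    t_end = max(sim_times)
    root = np.random.SeedSequence(int(spec.seed))
    patterns = []
    micrographs = [] if spec.render_images else None
    for rep, child in enumerate(root.spawn(spec.n_images)):
        sim_ss, noise_ss, render_ss = child.spawn(3)
        traj = run_until(truth, t_end=t_end, sample_times=sim_times,
                         rng=np.random.default_rng(sim_ss))
        noise_rng = np.random.default_rng(noise_ss)
        render_rng = np.random.default_rng(render_ss)
        by_time = {round(s.t, 6): s for s in traj.snapshots}
        for t_exp, t_sim in zip(spec.sample_times, sim_times):
            snap = by_time[round(t_sim, 6)]
            pts = _apply_detection_noise(snap.positions, truth.L,
                                         spec.jitter_sigma, spec.miss_rate,
                                         noise_rng)
            pat = PointPattern(pts, window,
                               meta={"time_h": t_exp, "replicate": rep,
                                     "N_true": snap.N})
            patterns.append(pat)
            if spec.render_images:
                from .imaging import render_nuclei
                micrographs.append(render_nuclei(pat, rng=render_rng))
    return SyntheticDataset(patterns, spec, micrographs)


def generate_poisson_null(N: int, window=(0.0, 0.0, 1000.0, 1000.0),
                          seed=None) -> PointPattern:
    """N iid uniform points in the window: the CSR null at fixed count."""
    if N < 2:
        raise ValueError("need N >= 2")
    rng = np.random.default_rng(seed)
    x0, y0, x1, y1 = window
    pts = rng.random((N, 2)) * np.array([x1 - x0, y1 - y0]) + np.array([x0, y0])
    return PointPattern(pts, window, meta={"null": "csr"})


def expected_initial_count(seeded_cells: float = 1e4, well_area: float = 1.93,
                           image_area: float = 1e-2):
    """Expected cells per image field from the seeding bookkeeping.

    Areas in cm^2.  Returns ``(exact, rounded)`` where ``rounded`` is the
    value to one significant figure (the 'about 50 cells' number).
    """
    if seeded_cells <= 0 or well_area <= 0 or image_area <= 0:
        raise ValueError("all inputs must be positive")
    exact = seeded_cells * image_area / well_area
    digits = int(np.floor(np.log10(abs(exact))))
    rounded = round(exact, -digits)
    return exact, rounded
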