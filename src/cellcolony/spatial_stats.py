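"""Ripley's K-function and related second-order summaries for point patterns.

K(r) is the expected number of further points within distance r of a typical
point, divided by the intensity; under complete spatial randomness (CSR)
K(r) = pi * r^2, so K(r)/r^2 plotted against r reads directly as a
correlation diagnostic: values above pi mean aggregation, below pi depletion.
The pair correlation function follows as g(r) = (1/2*pi*r) dK/dr.

The default analysis grid is r = 15..100 um in 5 um steps; distances below
15 um are excluded because two nucleus centroids closer than that cannot be
resolved reliably in the source images.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PointPattern",
    "KCurve",
    "DEFAULT_R_GRID",
    "ripley_k",
    "k_over_r2",
    "pair_correlation",
    "k_at_r",
    "bin_by_N",
]

DEFAULT_R_GRID = np.arange(15.0, 100.0 + 1e-9, 5.0)

EDGE_CORRECTIONS = ("none", "periodic", "translation")


class DegeneratePatternError(ValueError):
    """Raised when a pattern has too few points for a K estimate."""


@dataclass
class PointPattern:
    """Planar point pattern with its rectangular observation window (um)."""

    points: np.ndarray
    window: tuple  # (x_min, y_min, x_max, y_max)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        x0, y0, x1, y1 = self.window
        if not (x1 > x0 and y1 > y0):
            raise ValueError("window must have positive area")
        if self.points.size and (
            (self.points[:, 0] < x0 - 1e-9).any() or (self.points[:, 0] > x1 + 1e-9).any()
            or (self.points[:, 1] < y0 - 1e-9).any() or (self.points[:, 1] > y1 + 1e-9).any()
        ):
            raise ValueError("all points must lie inside the window")

    @property
    def N(self) -> int:
        return self.points.shape[0]

    @property
    def area(self) -> float:
        x0, y0, x1, y1 = self.window
        return (x1 - x0) * (y1 - y0)


@dataclass
class KCurve:
    """Ripley's K on an r-grid, with provenance of the source pattern."""

    r: np.ndarray
    K: np.ndarray
    N: float
    area: float
    edge_correction: str = "none"
    se: np.ndarray | None = None  # replicate SE when the curve is an average

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        self.K = np.asarray(self.K, dtype=float)
        if self.r.shape != self.K.shape:
            raise ValueError("r and K must have equal length")
        if self.r.size and (np.diff(self.r) <= 0).any():
            raise ValueError("r grid must be strictly increasing")
        if (self.r <= 0).any():
            raise ValueError("all r must be positive")


def _pair_quantities(pattern: PointPattern, edge_correction: str):
    """Distances (and translation weights) over ordered pairs, each unordered
    pair counted once with weight doubled."""
    pts = pattern.points
    x0, y0, x1, y1 = pattern.window
    lx, ly = x1 - x0, y1 - y0
    dx = pts[:, 0][:, None] - pts[:, 0][None, :]
    dy = pts[:, 1][:, None] - pts[:, 1][None, :]
    iu = np.triu_indices(pattern.N, k=1)
    dx, dy = dx[iu], dy[iu]
    if edge_correction == "periodic":
        dx -= lx * np.round(dx / lx)
        dy -= ly * np.round(dy / ly)
    d = np.hypot(dx, dy)
    if edge_correction == "translation":
        w = pattern.area / ((lx - np.abs(dx)) * (ly - np.abs(dy)))
    else:
        w = np.ones_like(d)
    return d, 2.0 * w  # double: ordered pairs


def ripley_k(pattern: PointPattern, r_grid=None, edge_correction: str = "none") -> KCurve:
    """Estimate K(r) = area / (N(N-1)) * sum_{i != j} w_ij 1(d_ij <= r).

    ``edge_correction``: 'none' (w=1, biased near the border), 'periodic'
    (minimum-image distances, exact for toroidal domains) or 'translation'
    (standard translation weights for bounded windows).
    """
    if edge_correction not in EDGE_CORRECTIONS:
        raise ValueError(f"edge_correction must be one of {EDGE_CORRECTIONS}")
    if pattern.N < 2:
        raise DegeneratePatternError("K requires at least 2 points")
    r_grid = DEFAULT_R_GRID if r_grid is None else np.asarray(r_grid, dtype=float)
    x0, y0, x1, y1 = pattern.window
    if edge_correction == "periodic" and r_grid.max() > 0.5 * min(x1 - x0, y1 - y0):
        warnings.warn("r grid exceeds half the window side; periodic K is biased there")
    d, w = _pair_quantities(pattern, edge_correction)
    order = np.argsort(d)
    d_sorted = d[order]
    cum_w = np.concatenate([[0.0], np.cumsum(w[order])])
    counts = cum_w[np.searchsorted(d_sorted, r_grid, side="right")]
    K = pattern.area / (pattern.N * (pattern.N - 1)) * counts
    return KCurve(r_grid, K, N=pattern.N, area=pattern.area,
                  edge_correction=edge_correction)


def k_over_r2(curve: KCurve) -> np.ndarray:
    """Element-wise K(r)/r^2; equals pi under CSR."""
    return curve.K / curve.r ** 2


def pair_correlation(curve: KCurve) -> np.ndarray:
    """g(r) = (1/2*pi*r) dK/dr by plain finite differences.

    Central differences at interior grid points, simple one-sided differences
    at the endpoints; no smoothing.  Exact for K quadratic in r.
    """
    r, K = curve.r, curve.K
    if r.size < 3:
        raise ValueError("need at least 3 grid points for g(r)")
    dK = np.empty_like(K)
    dK[1:-1] = (K[2:] - K[:-2]) / (r[2:] - r[:-2])
    dK[0] = (K[1] - K[0]) / (r[1] - r[0])
    dK[-1] = (K[-1] - K[-2]) / (r[-1] - r[-2])
    return dK / (2.0 * np.pi * r)


def k_at_r(curve: KCurve, r_star: float) -> float:
    """K(r*)/r*^2 by linear interpolation of K/r^2 on the grid."""
    if not (curve.r[0] <= r_star <= curve.r[-1]):
        raise ValueError(f"r_star = {r_star} outside grid [{curve.r[0]}, {curve.r[-1]}]")
    return float(np.interp(r_star, curve.r, k_over_r2(curve)))


def bin_by_N(samples, n_bins: int = 8, edges=None) -> pd.DataFrame:
    """Average scalar samples in equal-width bins of N.

    ``samples`` is an iterable of (N, value) pairs.  Bins span [min N, max N]
    (or use explicit ``edges``); the last bin is right-inclusive; empty bins
    are omitted.  Returns a DataFrame with columns
    ``N_center, mean, count, se`` (se = 0 for singleton bins).
    """
    arr = np.asarray(list(samples), dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one sample")
    N, v = arr[:, 0], arr[:, 1]
    if edges is None:
        lo, hi = N.min(), N.max()
        if hi == lo:
            hi = lo + 1.0  # single occupied bin
        edges = np.linspace(lo, hi, n_bins + 1)
    else:
        edges = np.asarray(edges, dtype=float)
        keep = (N >= edges[0]) & (N <= edges[-1])
        N, v = N[keep], v[keep]
        if N.size == 0:
            return pd.DataFrame(columns=["N_center", "mean", "count", "se"])
    idx = np.clip(np.digitize(N, edges) - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        sel = idx == b
        cnt = int(sel.sum())
        if cnt == 0:
            continue
        vals = v[sel]
        se = vals.std(ddof=1) / np.sqrt(cnt) if cnt > 1 else 0.0
        rows.append({"N_center": 0.5 * (edges[b] + edges[b + 1]),
                     "mean": vals.mean(), "count": cnt, "se": se})
    return pd.DataFrame(rows)
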