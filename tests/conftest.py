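import numpy as np
import pytest

from cellcolony import PointPattern


def naive_ripley_k(pattern: PointPattern, r_grid, edge_correction="none"):
    """Independent brute-force K: explicit double loop over ordered pairs."""
    pts = pattern.points
    n = pattern.N
    x0, y0, x1, y1 = pattern.window
    lx, ly = x1 - x0, y1 - y0
    area = lx * ly
    r_grid = np.asarray(r_grid, dtype=float)
    K = np.zeros_like(r_grid)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            dx = pts[j, 0] - pts[i, 0]
            dy = pts[j, 1] - pts[i, 1]
            if edge_correction == "periodic":
                dx -= lx * round(dx / lx)
                dy -= ly * round(dy / ly)
            d = np.hypot(dx, dy)
            if edge_correction == "translation":
                w = area / ((lx - abs(dx)) * (ly - abs(dy)))
            else:
                w = 1.0
            K += w * (d <= r_grid)
    return area / (n * (n - 1)) * K


class QueueRNG:
    """Deterministic stand-in for a Generator: replays preset uniforms."""

    def __init__(self, uniforms):
        self._u = list(uniforms)

    def random(self, size=None):
        if size is None:
            return self._u.pop(0)
        out = np.array([self._u.pop(0) for _ in range(int(size))])
        return out

    def standard_normal(self, size):
        return np.zeros(size)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
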