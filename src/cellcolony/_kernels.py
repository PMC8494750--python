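"""Numba-accelerated core loop of the colony simulation.

The kernel consumes the *same* ``numpy.random.Generator`` stream, in the same
order, as the pure-numpy step functions in :mod:`cellcolony.simulator`
(numba reproduces numpy Generator bit streams exactly), so the two engines
stay interchangeable and are tested against each other bit-for-bit.

Per-step draw order (must match ``step_motion`` / ``attempt_divisions``):
  1. ``2*N`` standard normals (x and y displacement of each cell, in order)
  2. ``N`` uniforms (per-cell division Bernoulli trials)
  3. one uniform per dividing cell (offspring angle), in cell-index order

Neighbour queries go through a cell-list grid (bin width >= 2*r0, linked
lists) so a step costs O(N) rather than O(N^2); at confluent densities the
brute-force scan would dominate the whole inference pipeline.  Bins may be
visited twice when the grid is narrower than 3 bins — harmless for the
boolean within-distance tests performed here.
"""

import numpy as np
from numba import njit

# status codes returned by run_segment
DONE_STEPS = 0      # exhausted the requested number of steps
DONE_TARGET = 1     # reached n >= n_target
DONE_FULL = 2       # position buffer too small to guarantee a safe step

_MAX_BINS = 128


@njit(cache=True, inline="always")
def _min_image(d, L, half):
    if d > half:
        return d - L
    if d < -half:
        return d + L
    return d


@njit(cache=True)
def _near(pos, head, nxt, nb, cs, x, y, skip, L, half, periodic, thresh_sq):
    """True iff some cell other than ``skip`` lies within sqrt(thresh_sq)."""
    bx = int(x / cs)
    by = int(y / cs)
    if bx >= nb:
        bx = nb - 1
    if by >= nb:
        by = nb - 1
    for ox in range(-1, 2):
        cx = bx + ox
        if periodic:
            cx = cx % nb
        elif cx < 0 or cx >= nb:
            continue
        for oy in range(-1, 2):
            cy = by + oy
            if periodic:
                cy = cy % nb
            elif cy < 0 or cy >= nb:
                continue
            j = head[cx * nb + cy]
            while j >= 0:
                if j != skip:
                    dx = pos[j, 0] - x
                    dy = pos[j, 1] - y
                    if periodic:
                        dx = _min_image(dx, L, half)
                        dy = _min_image(dy, L, half)
                    if dx * dx + dy * dy < thresh_sq:
                        return True
                j = nxt[j]
    return False


@njit(cache=True)
def run_segment(pos, n, lam, dt, D, tau0, T, N0, r0, L,
                density_dep, periodic, n_target, max_steps, rng, counters):
    """Advance the colony by up to ``max_steps`` steps, in place.

    ``pos`` is a pre-allocated ``(capacity, 2)`` buffer holding ``n`` cells.
    ``counters`` is an int64 array accumulating
    ``[steps_done, division_attempts, division_rejections]``.
    Returns ``(n, status)``.
    """
    cap = pos.shape[0]
    two_r0 = 2.0 * r0
    # strict '<' with a relative tie guard: a pair at distance exactly 2*r0
    # (every parent/offspring at birth) must not flip on rounding noise
    two_r0_sq = two_r0 * two_r0 * (1.0 - 1e-12)
    half = 0.5 * L
    two_L = 2.0 * L
    p_div = lam * dt
    sig_free = np.sqrt(2.0 * D * dt)
    steps = 0
    status = DONE_STEPS
    if n >= n_target:
        return n, DONE_TARGET

    nb = int(L // two_r0)
    if nb < 1:
        nb = 1
    elif nb > _MAX_BINS:
        nb = _MAX_BINS
    cs = L / nb
    head = np.empty(nb * nb, dtype=np.int64)
    nxt = np.empty(cap, dtype=np.int64)
    contact = np.empty(cap, dtype=np.bool_)

    while steps < max_steps:
        if 2 * n > cap:
            status = DONE_FULL
            break
        # adhesion factor from the population size at the start of the step
        if density_dep and n > N0:
            tau = 1.0 - (1.0 - tau0) * np.exp(-T * (n - N0))
        else:
            tau = tau0
        sig_contact = np.sqrt(2.0 * tau * D * dt)

        # cell-list of the frozen start-of-step configuration
        head[:] = -1
        for i in range(n):
            bx = int(pos[i, 0] / cs)
            by = int(pos[i, 1] / cs)
            if bx >= nb:
                bx = nb - 1
            if by >= nb:
                by = nb - 1
            b = bx * nb + by
            nxt[i] = head[b]
            head[b] = i

        for i in range(n):
            contact[i] = _near(pos, head, nxt, nb, cs, pos[i, 0], pos[i, 1],
                               i, L, half, periodic, two_r0_sq)

        xi = rng.standard_normal(2 * n)
        for i in range(n):
            s = sig_contact if contact[i] else sig_free
            x = pos[i, 0] + s * xi[2 * i]
            y = pos[i, 1] + s * xi[2 * i + 1]
            if periodic:
                pos[i, 0] = x % L
                pos[i, 1] = y % L
            else:
                x = x % two_L
                if x > L:
                    x = two_L - x
                y = y % two_L
                if y > L:
                    y = two_L - y
                pos[i, 0] = x
                pos[i, 1] = y

        # division attempts; offspring accepted this step take part in the
        # overlap checks of later attempts within the same step, so the
        # cell-list is rebuilt from the post-move positions and offspring
        # are threaded into it on acceptance
        u = rng.random(n)
        head[:] = -1
        for i in range(n):
            bx = int(pos[i, 0] / cs)
            by = int(pos[i, 1] / cs)
            if bx >= nb:
                bx = nb - 1
            if by >= nb:
                by = nb - 1
            b = bx * nb + by
            nxt[i] = head[b]
            head[b] = i
        n_old = n
        for i in range(n_old):
            if u[i] < p_div:
                counters[1] += 1
                ang = rng.random() * (2.0 * np.pi)
                ox = pos[i, 0] + two_r0 * np.cos(ang)
                oy = pos[i, 1] + two_r0 * np.sin(ang)
                if periodic:
                    ox = ox % L
                    oy = oy % L
                else:
                    ox = ox % two_L
                    if ox > L:
                        ox = two_L - ox
                    oy = oy % two_L
                    if oy > L:
                        oy = two_L - oy
                # the parent sits at distance exactly 2*r0 by construction;
                # a tie is non-overlap, so it is skipped rather than tested
                # on a floating-point knife edge
                if _near(pos, head, nxt, nb, cs, ox, oy, i, L, half,
                         periodic, two_r0_sq):
                    counters[2] += 1
                else:
                    pos[n, 0] = ox
                    pos[n, 1] = oy
                    bx = int(ox / cs)
                    by = int(oy / cs)
                    if bx >= nb:
                        bx = nb - 1
                    if by >= nb:
                        by = nb - 1
                    b = bx * nb + by
                    nxt[n] = head[b]
                    head[b] = n
                    n += 1
        steps += 1
        if n >= n_target:
            status = DONE_TARGET
            break
    counters[0] += steps
    return n, status
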