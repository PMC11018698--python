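"""Numba inner loops for the single-file channel simulator.

State is kept in fixed-capacity arrays: ``pos`` holds the ordered rod
centres, ``lab`` their origin labels (1 = entered from the left reservoir,
0 = from the right). Because identical hard rods cannot pass, labels are
attached to rank order: after positions are re-sorted, ``lab[i]`` still
names the i-th rod from the left (the sort-and-relabel rule, equivalent to
elastic exchange of identical rods).

Counter layout (int64):
    0 insertions left   1 insertions right
    2 removals left     3 removals right
    4 tracer removals left   5 tracer removals right
    6 occupancy sample count 7 occupancy rod-count sum
"""

from __future__ import annotations

import numpy as np
from numba import njit

SCHEME_SORT = 0
SCHEME_METROPOLIS = 1

N_COUNTERS = 8
C_INS_L, C_INS_R, C_REM_L, C_REM_R, C_TREM_L, C_TREM_R, C_OCC_N, C_OCC_SUM = range(8)


@njit(cache=True)
def _resolve_overlaps(pos, n, a):
    """Push overlapping neighbour pairs apart symmetrically until gap >= a.

    Pairwise elastic reflection for Brownian hard rods; with the step-size
    resolution condition (sigma < a/4) overlaps are shallow and a few
    sweeps suffice.
    """
    for _ in range(200):
        moved = False
        for i in range(n - 1):
            g = pos[i + 1] - pos[i]
            if g < a:
                s = 0.5 * (a - g)
                pos[i] -= s
                pos[i + 1] += s
                moved = True
        if not moved:
            break


@njit(cache=True)
def _insertion_sort(pos, n):
    for i in range(1, n):
        x = pos[i]
        j = i - 1
        while j >= 0 and pos[j] > x:
            pos[j + 1] = pos[j]
            j -= 1
        pos[j + 1] = x


@njit(cache=True)
def _try_insert(pos, lab, n, y, label, a):
    """Insert a rod at centre y with origin label if no overlap results."""
    k = 0
    while k < n and pos[k] < y:
        k += 1
    if k > 0 and y - pos[k - 1] < a:
        return n
    if k < n and pos[k] - y < a:
        return n
    for j in range(n, k, -1):
        pos[j] = pos[j - 1]
        lab[j] = lab[j - 1]
    pos[k] = y
    lab[k] = label
    return n + 1


@njit(cache=True)
def run_block(
    pos,
    lab,
    n,
    L,
    a,
    sigma,
    p_ins_l,
    p_ins_r,
    w,
    n_steps,
    sample_every,
    hist,
    counts,
    scheme,
    rng,
):
    """Advance the channel by ``n_steps`` timesteps; returns the rod count.

    Each step: Brownian displacement (sort-and-relabel or reject-overlap
    Metropolis), removal of rods whose centres left [0, L], then one
    insertion attempt per reservoir with probability ``p_ins_*`` at a
    uniform position inside the boundary zone of width ``w``.
    """
    nbins = hist.shape[0]
    cap = pos.shape[0]
    for step in range(n_steps):
        if scheme == SCHEME_SORT:
            for i in range(n):
                pos[i] += sigma * rng.standard_normal()
            _insertion_sort(pos, n)
            _resolve_overlaps(pos, n, a)
        else:
            for i in range(n):
                y = pos[i] + sigma * rng.standard_normal()
                ok = True
                if i > 0 and y - pos[i - 1] < a:
                    ok = False
                if i < n - 1 and pos[i + 1] - y < a:
                    ok = False
                if ok:
                    pos[i] = y

        # absorb rods whose centres left the channel
        while n > 0 and pos[0] < 0.0:
            counts[C_REM_L] += 1
            if lab[0] == 1:
                counts[C_TREM_L] += 1
            for j in range(1, n):
                pos[j - 1] = pos[j]
                lab[j - 1] = lab[j]
            n -= 1
        while n > 0 and pos[n - 1] > L:
            counts[C_REM_R] += 1
            if lab[n - 1] == 1:
                counts[C_TREM_R] += 1
            n -= 1

        # grand-canonical-style boundary insertion
        if n < cap - 1 and p_ins_l > 0.0 and rng.random() < p_ins_l:
            y = w * rng.random()
            n_new = _try_insert(pos, lab, n, y, 1, a)
            if n_new > n:
                counts[C_INS_L] += 1
                n = n_new
        if n < cap - 1 and p_ins_r > 0.0 and rng.random() < p_ins_r:
            y = L - w * rng.random()
            n_new = _try_insert(pos, lab, n, y, 0, a)
            if n_new > n:
                counts[C_INS_R] += 1
                n = n_new

        if sample_every > 0 and step % sample_every == 0:
            counts[C_OCC_N] += 1
            counts[C_OCC_SUM] += n
            for i in range(n):
                b = int(pos[i] / L * nbins)
                if b >= 0 and b < nbins:
                    hist[b] += 1
    return n


@njit(cache=True)
def free_trajectory(x0, sigma, n_steps, every, rng):
    """Trajectory of a single free rod (no boundaries), sampled every ``every`` steps."""
    n_out = n_steps // every
    out = np.empty(n_out)
    x = x0
    k = 0
    for step in range(1, n_steps + 1):
        x += sigma * rng.standard_normal()
        if step % every == 0:
            out[k] = x
            k += 1
    return out
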