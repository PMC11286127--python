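"""Numba inner loops for the random sequential update.

All randomness is drawn outside the kernels (numpy Generator per
realization); the kernels are deterministic given the draw arrays.
Direction codes: 0 -> +i, 1 -> -i, 2 -> +j, 3 -> -j.
"""
import numpy as np
from numba import njit


@njit(cache=True, inline="always")
def _g_eval(gtab, s):
    # linear interpolation on a uniform table over [0,1]; exact for identity g
    m = gtab.shape[0] - 1
    x = s * m
    c = int(x)
    if c >= m:
        return gtab[m]
    f = x - c
    return gtab[c] * (1.0 - f) + gtab[c + 1] * f


@njit(cache=True)
def motility_kernel(occ, sub, pos, P, gtab, agent_idx, attempt_u, dirs):
    """One motility phase: sequential attempted moves, exclusion enforced.

    Later draws see earlier moves through `occ`/`pos`; `sub` is read-only
    within the phase (deposition is a separate phase).
    """
    W, H = occ.shape
    for k in range(agent_idx.shape[0]):
        a = agent_idx[k]
        i = pos[a, 0]
        j = pos[a, 1]
        if attempt_u[k] >= P * _g_eval(gtab, sub[i, j]):
            continue
        d = dirs[k]
        ni = i
        nj = j
        if d == 0:
            ni += 1
        elif d == 1:
            ni -= 1
        elif d == 2:
            nj += 1
        else:
            nj -= 1
        if ni < 0 or ni >= W or nj < 0 or nj >= H:
            continue  # reflecting boundary: off-lattice target aborts the move
        if occ[ni, nj] == 0:
            occ[i, j] = 0
            occ[ni, nj] = 1
            pos[a, 0] = ni
            pos[a, 1] = nj


@njit(cache=True)
def proliferation_kernel(occ, pos, n0, Q, agent_idx, attempt_u, dirs):
    """One proliferation phase; returns the new agent count.

    Draws are over the n0 agents present at phase start; daughters are
    appended at pos[n0:] and are not selectable until the next step.
    Occupied targets abort the event (crowding).
    """
    W, H = occ.shape
    n = n0
    for k in range(agent_idx.shape[0]):
        if attempt_u[k] >= Q:
            continue
        a = agent_idx[k]
        i = pos[a, 0]
        j = pos[a, 1]
        d = dirs[k]
        ni = i
        nj = j
        if d == 0:
            ni += 1
        elif d == 1:
            ni -= 1
        elif d == 2:
            nj += 1
        else:
            nj -= 1
        if ni < 0 or ni >= W or nj < 0 or nj >= H:
            continue
        if occ[ni, nj] == 0:
            occ[ni, nj] = 1
            pos[n, 0] = ni
            pos[n, 1] = nj
            n += 1
    return n
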