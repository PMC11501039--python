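"""Numba-compiled inner loops of the Monte Carlo engine.

The engine draws, for every elementary update, exactly four values from a
single ``numpy.random.Generator`` stream, in a fixed order:

1. the flat index of site i (skipped when the caller forces i),
2. the direction of neighbour j among (up, down, left, right)
   (skipped when forced),
3. the branch uniform (division attempt vs. fate switch),
4. the outcome uniform (A vs. B).

Draws 3 and 4 are consumed even when the update turns out to be blocked, so
a trajectory is a pure function of (initial grid, parameters, seed) and the
pure-Python single-update path in :mod:`epifate.dynamics` replays the exact
same stream as the compiled multi-step kernel.

Spins are int8; parameters arrive as plain scalars so the kernels have a
single stable signature.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# outcome codes shared with epifate.dynamics
DIVISION_AA = 0
DIVISION_BB = 1
DIVISION_BLOCKED = 2
SWITCH_TO_A = 3
SWITCH_TO_B = 4

# variant codes
VARIANT_C = 0
VARIANT_R = 1

# interaction form codes
FORM_LOGISTIC = 0
FORM_HILL = 1


@njit(cache=True, inline="always")
def _p_A(n, J, form):
    x = J * n
    if form == FORM_LOGISTIC:
        return 0.5 * (1.0 + np.tanh(x))
    return 0.5 * (1.0 + x / (1.0 + abs(x)))


@njit(cache=True, inline="always")
def _neighbor_field(cells, L, k, l):
    return (
        cells[(k - 1) % L, l]
        + cells[(k + 1) % L, l]
        + cells[k, (l - 1) % L]
        + cells[k, (l + 1) % L]
    )


@njit(cache=True)
def micro_update(cells, q, variant, form, J, rng, force_i, force_jdir):
    """One elementary update; mutates ``cells`` in place.

    ``force_i`` (flat site index) and ``force_jdir`` (0..3) replace the
    corresponding random draws when >= 0.  Returns
    ``(outcome_code, i_flat, j_flat)``.
    """
    L = cells.shape[0]
    N = L * L
    if force_i >= 0:
        idx = force_i
    else:
        idx = rng.integers(0, N)
    if force_jdir >= 0:
        jdir = force_jdir
    else:
        jdir = rng.integers(0, 4)
    u_branch = rng.random()
    u_outcome = rng.random()

    ik = idx // L
    il = idx % L
    if jdir == 0:
        jk, jl = (ik - 1) % L, il
    elif jdir == 1:
        jk, jl = (ik + 1) % L, il
    elif jdir == 2:
        jk, jl = ik, (il - 1) % L
    else:
        jk, jl = ik, (il + 1) % L
    jflat = jk * L + jl

    if u_branch < q:
        # division attempt: needs an (A, B) pair; the extruded cell is
        # replaced by a daughter, so both sites end up with the same type
        ci = cells[ik, il]
        cj = cells[jk, jl]
        if ci == cj:
            return DIVISION_BLOCKED, idx, jflat
        if variant == VARIANT_C:
            n6 = (
                _neighbor_field(cells, L, ik, il)
                + _neighbor_field(cells, L, jk, jl)
                - ci
                - cj
            )
            p = _p_A(n6, J, form)
        else:
            p = 0.5
        if u_outcome < p:
            cells[ik, il] = 1
            cells[jk, jl] = 1
            return DIVISION_AA, idx, jflat
        cells[ik, il] = -1
        cells[jk, jl] = -1
        return DIVISION_BB, idx, jflat

    # division-independent fate switch on site i alone; the new type is
    # drawn afresh (memoryless), valid because p_A + p_B = 1
    n4 = _neighbor_field(cells, L, ik, il)
    p = _p_A(n4, J, form)
    if u_outcome < p:
        cells[ik, il] = 1
        return SWITCH_TO_A, idx, jflat
    cells[ik, il] = -1
    return SWITCH_TO_B, idx, jflat


@njit(cache=True)
def run_mcs(cells, q, variant, form, J, n_mcs, rng, early_exit):
    """Apply ``n_mcs`` Monte Carlo steps (L*L updates each) in place.

    With ``early_exit`` the loop stops once the grid is uniform (checked
    after each MCS); only correct when uniform grids are absorbing.
    Returns ``(elapsed_mcs, absorbed)``.
    """
    L = cells.shape[0]
    N = L * L
    for step in range(n_mcs):
        for _ in range(N):
            micro_update(cells, q, variant, form, J, rng, -1, -1)
        if early_exit:
            total = 0
            for k in range(L):
                for l in range(L):
                    total += cells[k, l]
            if total == N or total == -N:
                return step + 1, True
    return n_mcs, False
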