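"""Order parameters for macroscopic patch and checkerboard order.

``phi = |N_A - N_B| / (N_A + N_B)`` detects system-spanning single-type
patches: for small patches and large L the two types balance and phi -> 0,
while a dominating macroscopic cluster keeps phi > 0.  The staggered order
parameter ``phi~`` is phi evaluated after flipping spins on the odd
sublattice, so macroscopic checkerboard patterns appear as uniform patches
and register as phi~ > 0.

Both are endpoint observables of a single configuration; ensemble means and
standard errors over replicates live in :mod:`epifate.experiments`.
"""

from __future__ import annotations

import numpy as np

from .lattice import CellGrid, staggered_mask, validate_grid

__all__ = ["order_parameter", "staggered_order_parameter", "cell_counts"]


def cell_counts(grid: CellGrid) -> tuple[int, int]:
    """(N_A, N_B): numbers of +1 and -1 sites; they sum to L**2."""
    grid = validate_grid(grid)
    n_a = int((grid == 1).sum())
    return n_a, grid.size - n_a


def order_parameter(grid: CellGrid) -> float:
    """phi = |sum_i c_i| / L**2 = |N_A - N_B| / (N_A + N_B), in [0, 1]."""
    grid = validate_grid(grid)
    return abs(int(grid.sum())) / grid.size


def staggered_order_parameter(grid: CellGrid) -> float:
    """phi~ = |sum_i (-1)**(k_i + l_i) c_i| / L**2, in [0, 1].

    Identical to ``order_parameter(staggered_transform(grid))``; requires
    even L so the checkerboard mask wraps consistently.
    """
    grid = validate_grid(grid)
    masked = grid * staggered_mask(grid.shape[0])
    return abs(int(masked.sum())) / grid.size
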