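"""Square-lattice state, neighbourhood geometry, and snapshot I/O.

A cell sheet is represented as an ``L x L`` numpy array of spins
``c_i in {+1, -1}``: ``+1`` marks a self-renewing (type A) cell and ``-1``
a cell licensed or committed to differentiation (type B).  The lattice is
fully occupied at all times — the dynamics never create vacancies.

Boundary conditions are periodic on both axes and the neighbourhood is the
von Neumann one (up/down/left/right), so every site has exactly four
neighbours and every adjacent pair of sites has six distinct exterior
neighbours.  ``L`` is restricted to even values so that a checkerboard
pattern (and therefore the staggered transform) is globally consistent
across the periodic seam.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

__all__ = [
    "CellGrid",
    "make_grid",
    "validate_grid",
    "neighbor_field",
    "pair_neighbor_field",
    "staggered_transform",
    "staggered_mask",
    "write_snapshot",
    "read_snapshot",
]

#: A cell grid is an ``(L, L)`` int8 array with values in {+1, -1}.
CellGrid = np.ndarray

GRID_DTYPE = np.int8

_MODES = ("random", "all_A", "all_B", "checkerboard")

# von Neumann offsets, in the fixed order used by the update engine:
# up, down, left, right (row 0 is the top row in snapshot files).
NEIGHBOR_OFFSETS = ((-1, 0), (1, 0), (0, -1), (0, 1))


def _check_L(L: int) -> int:
    L = int(L)
    if L < 2 or L % 2 != 0:
        raise ValueError(
            f"lattice edge length must be an even integer >= 2, got L={L}; "
            "even L is required for a globally consistent checkerboard under "
            "periodic boundaries"
        )
    return L


def make_grid(L: int, mode: str = "random", seed: int | None = None) -> CellGrid:
    """Create an ``L x L`` spin grid.

    Parameters
    ----------
    L
        Even lattice edge length (``N = L**2`` sites).
    mode
        ``"random"`` — each site independently +1/-1 with probability 1/2
        (the standard initial condition); ``"all_A"`` / ``"all_B"`` —
        uniform grids; ``"checkerboard"`` — ``c_i = (-1)**(k_i + l_i)``.
    seed
        Seed for the random mode (ignored otherwise).
    """
    L = _check_L(L)
    if mode == "random":
        rng = np.random.default_rng(seed)
        return (2 * rng.integers(0, 2, size=(L, L)) - 1).astype(GRID_DTYPE)
    if mode == "all_A":
        return np.ones((L, L), dtype=GRID_DTYPE)
    if mode == "all_B":
        return -np.ones((L, L), dtype=GRID_DTYPE)
    if mode == "checkerboard":
        return staggered_mask(L)
    raise ValueError(f"unknown grid mode {mode!r}; expected one of {_MODES}")


def validate_grid(grid: CellGrid) -> CellGrid:
    """Check the grid invariants (square, even L, spins in {+1,-1})."""
    grid = np.asarray(grid)
    if grid.ndim != 2 or grid.shape[0] != grid.shape[1]:
        raise ValueError(f"grid must be square, got shape {grid.shape}")
    _check_L(grid.shape[0])
    if not np.isin(grid, (-1, 1)).all():
        raise ValueError("grid sites must all be +1 or -1")
    return grid


def staggered_mask(L: int) -> np.ndarray:
    """The checkerboard sign mask ``(-1)**(k + l)`` with +1 at (0, 0)."""
    L = _check_L(L)
    k, l = np.indices((L, L))
    return np.where((k + l) % 2 == 0, 1, -1).astype(GRID_DTYPE)


def neighbor_field(grid: CellGrid, site: tuple[int, int]) -> int:
    """Sum of spins over the 4 von Neumann neighbours of ``site``.

    Equals ``n_A(i) - n_B(i)``, the excess of type-A neighbours; always
    even and in ``[-4, 4]``.
    """
    L = grid.shape[0]
    k, l = site
    k %= L
    l %= L
    total = 0
    for dk, dl in NEIGHBOR_OFFSETS:
        total += int(grid[(k + dk) % L, (l + dl) % L])
    return total


def pair_neighbor_field(
    grid: CellGrid, i: tuple[int, int], j: tuple[int, int]
) -> int:
    """Sum of spins over the 6 exterior neighbours of an adjacent pair.

    The exterior neighbourhood consists of all von Neumann neighbours of
    ``i`` or ``j`` excluding the pair itself (3 per member).  ``i`` and
    ``j`` must be lattice neighbours under periodic wrapping.
    """
    L = grid.shape[0]
    ik, il = i[0] % L, i[1] % L
    jk, jl = j[0] % L, j[1] % L
    dk = (jk - ik) % L
    dl = (jl - il) % L
    adjacent = (dk, dl) in {(0, 1), (0, L - 1), (1, 0), (L - 1, 0)}
    if not adjacent or (ik, il) == (jk, jl):
        raise ValueError(f"sites {i} and {j} are not lattice neighbours")
    total = 0
    for ck, cl in ((ik, il), (jk, jl)):
        for ok, ol in NEIGHBOR_OFFSETS:
            nk, nl = (ck + ok) % L, (cl + ol) % L
            if (nk, nl) == (ik, il) or (nk, nl) == (jk, jl):
                continue
            total += int(grid[nk, nl])
    return total


def staggered_transform(grid: CellGrid) -> CellGrid:
    """Flip spins on the odd sublattice: ``c~_i = (-1)**(k_i + l_i) c_i``.

    An involution; it maps checkerboard order to uniform order, so the
    ordinary order parameter of the transformed grid measures checkerboard
    order of the original.
    """
    grid = validate_grid(grid)
    return (grid * staggered_mask(grid.shape[0])).astype(GRID_DTYPE)


_CHAR_FOR_SPIN = {1: "A", -1: "B"}
_SPIN_FOR_CHAR = {"A": 1, "B": -1}


def write_snapshot(
    grid: CellGrid, path, metadata: Mapping[str, object] | None = None
) -> None:
    """Write a grid to a plain-text snapshot file.

    Format: ``#``-prefixed ``key=value`` header lines (``L`` always
    present), then ``L`` rows of ``L`` characters over the alphabet
    ``{A, B}``, row ``k`` on line ``k``.
    """
    grid = validate_grid(grid)
    L = grid.shape[0]
    lines = [f"# L={L}"]
    for key, value in (metadata or {}).items():
        if key == "L":
            continue
        lines.append(f"# {key}={value}")
    for row in grid:
        lines.append("".join(_CHAR_FOR_SPIN[int(c)] for c in row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_snapshot(path) -> tuple[CellGrid, dict[str, str]]:
    """Read a snapshot file; returns ``(grid, metadata)``.

    Malformed files (bad header, wrong row length, characters outside
    ``{A, B}``, wrong row count) are rejected with the offending line
    number in the message.
    """
    metadata: dict[str, str] = {}
    rows: list[list[int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if rows:
                    raise ValueError(
                        f"{path}: line {lineno}: header line after grid rows"
                    )
                body = line[1:].strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    metadata[key.strip()] = value.strip()
                continue
            try:
                rows.append([_SPIN_FOR_CHAR[ch] for ch in line])
            except KeyError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: character {exc.args[0]!r} outside "
                    "alphabet {A, B}"
                ) from None
    if "L" not in metadata:
        raise ValueError(f"{path}: missing 'L' header line")
    try:
        L = int(metadata["L"])
    except ValueError:
        raise ValueError(f"{path}: header L={metadata['L']!r} is not an integer")
    if len(rows) != L:
        raise ValueError(f"{path}: header L={L} but found {len(rows)} grid rows")
    for k, row in enumerate(rows):
        if len(row) != L:
            raise ValueError(
                f"{path}: grid row {k} has length {len(row)}, expected L={L}"
            )
    grid = np.array(rows, dtype=GRID_DTYPE)
    return validate_grid(grid), metadata
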