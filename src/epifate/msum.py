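"""Mapping onto memoryless spin-update models (MSUM).

A MSUM updates a uniformly chosen site to +1 with a probability p_+ that
depends only on the neighbour field n of the site — not on its own prior
state — and satisfies p_+(-n) = 1 - p_+(n).  On the square lattice with
four neighbours the whole model is then fixed by two numbers,

    p1 = p_+(2),   p2 = p_+(4),

and the (p1, p2) plane carries an order/disorder phase transition of the
Ising universality class, except at the voter point (3/4, 1).

Both cell-fate variants map onto this plane:

* variant R maps exactly, per Monte Carlo time unit:
      p_+(n) = q (n + 4) / 8 + (1 - q) p_A(n)
* variant C maps in steady state, counting only the four neighbours of the
  updated site:
      p_+(n) = (n + 4) p_A(n) / [(n + 4) p_A(n) + (4 - n) p_A(-n)]
  which pins p2 = 1 for every J and both interaction forms; at J = 0 the
  trajectory sits exactly on the voter point.

For variant R at q = 0 with the logistic form, p_+(n) is the heat-bath
(Glauber) rule of the 2D Ising model with coupling J, so the order/disorder
transition occurs at the exactly known critical coupling
J_c = ln(1 + sqrt(2)) / 2.

A symmetric division inside a checkerboard-ordered region flips one site of
the pattern, which on the staggered lattice acts like a forced update
against a fully aligned neighbourhood; this lowers p2 by q, i.e. shifts the
phase-plane position (p1, p2) -> (p1, p2 - q).  The phase transition LINE
itself has no known closed form and is not computed here.
"""

from __future__ import annotations

import math
from typing import Iterable, NamedTuple

import pandas as pd

from .interactions import InteractionSpec, fate_probability_A

__all__ = [
    "MSUMPoint",
    "update_probability",
    "msum_point",
    "staggered_shift",
    "trajectory",
    "ISING_CRITICAL_COUPLING",
]

#: Exact critical coupling of the 2D square-lattice Ising model under
#: heat-bath dynamics, ln(1 + sqrt(2)) / 2 ~= 0.4407.
ISING_CRITICAL_COUPLING = math.log(1.0 + math.sqrt(2.0)) / 2.0


class MSUMPoint(NamedTuple):
    """Position (p1, p2) in the MSUM phase plane."""

    p1: float
    p2: float

    @property
    def is_valid(self) -> bool:
        """Whether both coordinates are valid probabilities."""
        return 0.0 <= self.p1 <= 1.0 and 0.0 <= self.p2 <= 1.0


#: The voter model sits at this point of the phase plane.
VOTER_POINT = MSUMPoint(0.75, 1.0)


def update_probability(
    variant: str, spec: InteractionSpec, q: float, n: int
) -> float:
    """Effective memoryless update probability p_+(n) for a single site.

    ``n`` must be even with |n| <= 4 (four-neighbour field).  Variant C
    ignores ``q`` (its mapping holds in steady state, where time units drop
    out); variant R uses the per-MCS probability with q = lambda/(lambda+omega).
    """
    n = int(n)
    if n % 2 != 0 or abs(n) > 4:
        raise ValueError(f"n must be even with |n| <= 4, got {n}")
    p_a = fate_probability_A(spec, n)
    if variant == "R":
        if not 0.0 <= q <= 1.0:
            raise ValueError(f"q must be in [0, 1], got {q}")
        return q * (n + 4) / 8.0 + (1.0 - q) * p_a
    if variant == "C":
        p_a_neg = fate_probability_A(spec, -n)
        num = (n + 4) * p_a
        den = num + (4 - n) * p_a_neg
        return num / den
    raise ValueError(f"variant must be 'C' or 'R', got {variant!r}")


def msum_point(variant: str, spec: InteractionSpec, q: float = 1.0) -> MSUMPoint:
    """Phase-plane position (p1, p2) = (p_+(2), p_+(4)) of a model."""
    return MSUMPoint(
        update_probability(variant, spec, q, 2),
        update_probability(variant, spec, q, 4),
    )


def staggered_shift(point: MSUMPoint, q: float) -> MSUMPoint:
    """Effect of symmetric divisions on staggered (checkerboard) order.

    Returns (p1, p2 - q) without clamping; check ``.is_valid`` on the
    result — p2 - q < 0 means the shift left the probability plane.
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"q must be in [0, 1], got {q}")
    return MSUMPoint(point.p1, point.p2 - q)


def trajectory(
    variant: str, form: str, q: float, J_grid: Iterable[float]
) -> pd.DataFrame:
    """Phase-plane trajectory p(J) = (p1(J), p2(J)) along a J grid.

    Returns a DataFrame with columns (J, p1, p2), one row per J in the
    given order, suitable for plotting over the phase diagram.  Variant C
    trajectories lie on the top edge p2 = 1.
    """
    rows = []
    for J in J_grid:
        point = msum_point(variant, InteractionSpec(form, float(J)), q)
        rows.append({"J": float(J), "p1": point.p1, "p2": point.p2})
    return pd.DataFrame(rows, columns=["J", "p1", "p2"])
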