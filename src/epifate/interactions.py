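"""Juxtacrine fate-choice probabilities p_A(n), p_B(n).

The probability that a cell adopts the self-renewing type A depends on the
spin field of its neighbours, n = n_A - n_B, through a sigmoidal function of
signalling strength J.  Positive J is lateral induction (neighbours promote
their own type), negative J lateral inhibition, and J = 0 removes the
interaction entirely.  Two functional forms are supported:

* ``logistic``: p_A(n) = (1 + tanh(J n)) / 2 — exponential saturation; this
  is exactly the heat-bath (Glauber) acceptance probability of a 2D Ising
  model with coupling J.
* ``hill``:     p_A(n) = (1 + J n / (1 + |J n|)) / 2 — algebraic saturation,
  a symmetrised Michaelis-Menten (Hill exponent 1) form.

Both satisfy p_A(-n) = 1 - p_A(n), hence p_A(0) = 1/2 and neutral A/B
competition, the condition for a homeostatic tissue.  p_B is never stored:
it is always 1 - p_A, which makes the symmetry unviolable.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np

__all__ = ["InteractionSpec", "fate_probability_A", "fate_probability_B", "FORMS"]

FORMS = ("logistic", "hill")


@dataclass(frozen=True)
class InteractionSpec:
    """Interaction form plus signed signalling strength J.

    J may be any finite real; the probability formulas saturate safely for
    arbitrarily large |J|.
    """

    form: str
    J: float

    def __post_init__(self):
        if self.form not in FORMS:
            raise ValueError(f"form must be one of {FORMS}, got {self.form!r}")
        if not math.isfinite(self.J):
            raise ValueError(f"J must be finite, got {self.J}")


def fate_probability_A(spec: InteractionSpec, n) -> float | np.ndarray:
    """Probability that an updated cell becomes type A given neighbour field n.

    Accepts scalar or array ``n``; the formulas extrapolate to any integer
    n even though a site sees at most |n| = 4 (or 6 for a dividing pair).
    """
    x = spec.J * np.asarray(n, dtype=float)
    if spec.form == "logistic":
        p = 0.5 * (1.0 + np.tanh(x))
    else:
        p = 0.5 * (1.0 + x / (1.0 + np.abs(x)))
    if np.ndim(n) == 0:
        return float(p)
    return p


def fate_probability_B(spec: InteractionSpec, n) -> float | np.ndarray:
    """p_B(n) = 1 - p_A(n) = p_A(-n)."""
    return 1.0 - fate_probability_A(spec, n)
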