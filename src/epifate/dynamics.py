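"""Monte Carlo engine for the two cell-fate model variants.

The tissue evolves as a continuous-time Markov process realized by random
sequential update: during one Monte Carlo step (MCS) the engine picks
``N = L**2`` times a site i and one of its four neighbours j, uniformly at
random, and attempts one event.  With probability ``q`` the attempt is a
division-coupled replacement — possible only on an (A, B) pair, in which
case the B cell is extruded and the dividing neighbour's daughters occupy
both sites, choosing a common fate; with probability ``1 - q`` it is a
division-independent fate switch of site i alone.  Rates are normalized to
``lambda + omega = 1`` so that ``q = lambda / (lambda + omega)`` is the only
rate parameter and one MCS advances time by one unit.

Variant C ("committed"): fate is decided at division, so ``q = 1`` and the
division outcome follows the signalling interaction evaluated on the six
exterior neighbours of the pair.  Uniform grids are absorbing.

Variant R ("reversible"): division outcomes are unbiased (p = 1/2) and the
interaction instead governs the fate switches, evaluated on the four
neighbours of the switching site.  For q < 1 no configuration is absorbing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .interactions import InteractionSpec, fate_probability_A
from .lattice import CellGrid, make_grid, validate_grid
from .observables import order_parameter, staggered_order_parameter

__all__ = [
    "ModelConfig",
    "RunResult",
    "micro_update",
    "monte_carlo_step",
    "run_simulation",
    "single_site_rates",
]

_OUTCOME_TAGS = {
    _kernels.DIVISION_AA: "division_AA",
    _kernels.DIVISION_BB: "division_BB",
    _kernels.DIVISION_BLOCKED: "division_blocked",
    _kernels.SWITCH_TO_A: "switch_to_A",
    _kernels.SWITCH_TO_B: "switch_to_B",
}

_VARIANT_CODES = {"C": _kernels.VARIANT_C, "R": _kernels.VARIANT_R}
_FORM_CODES = {"logistic": _kernels.FORM_LOGISTIC, "hill": _kernels.FORM_HILL}


@dataclass(frozen=True)
class ModelConfig:
    """One complete simulation parameterization.

    ``q`` is the proportion of symmetric-division attempts.  Variant C has
    no division-independent switching (omega = 0), so q is forced to 1.
    """

    variant: str
    interaction: InteractionSpec
    L: int
    runtime_mcs: int
    seed: int
    q: float = 1.0

    def __post_init__(self):
        if self.variant not in _VARIANT_CODES:
            raise ValueError(f"variant must be 'C' or 'R', got {self.variant!r}")
        if self.variant == "C" and self.q != 1.0:
            raise ValueError("variant C has omega = 0, which forces q = 1")
        if not 0.0 <= self.q <= 1.0:
            raise ValueError(f"q must be in [0, 1], got {self.q}")
        if self.L < 2 or self.L % 2 != 0:
            raise ValueError(f"L must be an even integer >= 2, got {self.L}")
        if self.runtime_mcs < 0:
            raise ValueError(f"runtime_mcs must be >= 0, got {self.runtime_mcs}")

    @property
    def _codes(self) -> tuple[int, int, float, float]:
        return (
            _VARIANT_CODES[self.variant],
            _FORM_CODES[self.interaction.form],
            float(self.interaction.J),
            float(self.q),
        )


@dataclass
class RunResult:
    """Outcome of one simulation run."""

    grid: CellGrid
    elapsed_mcs: int
    absorbed: bool
    #: rows of (mcs, phi, phi_staggered) when sampling was requested
    time_series: list[tuple[int, float, float]] = field(default_factory=list)


def micro_update(
    grid: CellGrid,
    config: ModelConfig,
    rng: np.random.Generator,
    i: tuple[int, int] | None = None,
    j_direction: int | None = None,
) -> str:
    """Apply one elementary update in place; returns the outcome tag.

    ``i`` forces the primary site and ``j_direction`` (0=up, 1=down,
    2=left, 3=right) forces the neighbour choice; either skips the
    corresponding RNG draw.  With both left unset, L**2 successive calls
    consume the stream exactly like one :func:`monte_carlo_step`.
    """
    variant, form, J, q = config._codes
    L = grid.shape[0]
    force_i = -1 if i is None else (i[0] % L) * L + (i[1] % L)
    force_j = -1 if j_direction is None else int(j_direction)
    code, _, _ = _kernels.micro_update(grid, q, variant, form, J, rng, force_i, force_j)
    return _OUTCOME_TAGS[code]


def monte_carlo_step(
    grid: CellGrid, config: ModelConfig, rng: np.random.Generator
) -> CellGrid:
    """Apply exactly L**2 elementary updates in place (one time unit)."""
    variant, form, J, q = config._codes
    _kernels.run_mcs(grid, q, variant, form, J, 1, rng, False)
    return grid


def _uniform(grid: CellGrid) -> bool:
    s = int(grid.sum())
    return abs(s) == grid.size


def run_simulation(
    config: ModelConfig,
    initial: CellGrid | None = None,
    early_exit: bool = False,
    sample_stride: int | None = None,
) -> RunResult:
    """Run a full simulation from a random (or supplied) initial grid.

    ``early_exit`` stops as soon as the grid is uniform; this is only a
    valid optimization when uniform grids are absorbing (variant C, or
    variant R at q = 1), and it is off by default.  ``sample_stride``
    records (mcs, phi, phi_staggered) every that many MCS.
    """
    if early_exit and not (config.variant == "C" or config.q == 1.0):
        raise ValueError(
            "early_exit is only valid when uniform grids are absorbing "
            "(variant C, or variant R with q = 1)"
        )
    rng = np.random.default_rng(config.seed)
    if initial is None:
        grid = (2 * rng.integers(0, 2, size=(config.L, config.L)) - 1).astype(np.int8)
    else:
        grid = validate_grid(initial).astype(np.int8).copy()
        if grid.shape[0] != config.L:
            raise ValueError(
                f"initial grid has L={grid.shape[0]} but config.L={config.L}"
            )
    variant, form, J, q = config._codes

    series: list[tuple[int, float, float]] = []
    stride = config.runtime_mcs if not sample_stride else int(sample_stride)

    elapsed = 0
    absorbed = early_exit and _uniform(grid)
    if sample_stride:
        series.append((0, order_parameter(grid), staggered_order_parameter(grid)))
    while elapsed < config.runtime_mcs and not absorbed:
        chunk = min(stride, config.runtime_mcs - elapsed)
        done, absorbed = _kernels.run_mcs(
            grid, q, variant, form, J, chunk, rng, early_exit
        )
        elapsed += done
        if sample_stride:
            series.append(
                (elapsed, order_parameter(grid), staggered_order_parameter(grid))
            )
    return RunResult(grid=grid, elapsed_mcs=elapsed, absorbed=bool(absorbed), time_series=series)


def run_to_absorption(
    config: ModelConfig, max_mcs: int = 10**6, initial: CellGrid | None = None
) -> RunResult:
    """Run until the grid is uniform (absorbing), up to ``max_mcs`` MCS.

    Convenience wrapper for absorbing dynamics such as variant C; the
    configured ``runtime_mcs`` is ignored in favour of ``max_mcs``.
    """
    cfg = ModelConfig(
        variant=config.variant,
        interaction=config.interaction,
        L=config.L,
        runtime_mcs=int(max_mcs),
        seed=config.seed,
        q=config.q,
    )
    return run_simulation(cfg, initial=initial, early_exit=True)


def single_site_rates(n4: int, config: ModelConfig) -> tuple[float, float]:
    """Analytic per-site transition rates (gamma_A, gamma_B) at neighbour field n4.

    Under the mean-pair approximation the probability that a random
    neighbour of the site is type A is ``f_A = (n4 + 4) / 8``, and

        gamma_A(n) = f_A * 2 * lambda * p_A^div + omega * p_A^switch
        gamma_B(n) = gamma_A(-n)

    with lambda = q, omega = 1 - q.  The factor 2 counts that a pair event
    can be triggered with the site in either role.  These rates are the
    oracle against which empirical update frequencies are tested; the
    simulator itself never uses them.
    """
    n4 = int(n4)
    if n4 % 2 != 0 or abs(n4) > 4:
        raise ValueError(f"n4 must be even with |n4| <= 4, got {n4}")

    def gamma_A(n: int) -> float:
        f_A = (n + 4) / 8.0
        if config.variant == "C":
            p_div = fate_probability_A(config.interaction, n)
            p_switch = 0.0
        else:
            p_div = 0.5
            p_switch = fate_probability_A(config.interaction, n)
        lam, omega = config.q, 1.0 - config.q
        return f_A * 2.0 * lam * p_div + omega * p_switch

    return gamma_A(n4), gamma_A(-n4)
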