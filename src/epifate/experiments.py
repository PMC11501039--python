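"""Replicated parameter sweeps and finite-size scaling protocols.

Each sweep point runs ``R`` independent simulations (replicate r uses seed
``base_seed + r``), measures the endpoint order parameters phi and phi~ of
every run, and reports their means with standard errors (SEM = sd / sqrt(R),
unbiased variance).  The reference protocol uses L = 80, R = 80 and
4000 MCS per run; the default desk-scale protocol (L = 40, R = 20,
800 MCS) resolves the same qualitative phase behaviour in minutes on one
CPU.  Finite-size scaling runs use runtimes of L**2 / 2 MCS so that the
equilibration window grows with the system.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import sqrt
from typing import Sequence

import numpy as np
import pandas as pd

from .dynamics import ModelConfig, run_simulation
from .interactions import InteractionSpec
from .observables import order_parameter, staggered_order_parameter

__all__ = [
    "SweepSpec",
    "ObservableRecord",
    "summarize",
    "run_sweep",
    "run_scaling",
    "RECORD_COLUMNS",
]

RECORD_COLUMNS = [
    "variant",
    "form",
    "J",
    "q",
    "L",
    "R",
    "runtime_mcs",
    "mean_phi",
    "sem_phi",
    "mean_phi_staggered",
    "sem_phi_staggered",
]

#: sentinel for the Fig-4-style runtime rule runtime = L**2 / 2
HALF_L_SQUARED = "half_L_squared"


@dataclass(frozen=True)
class SweepSpec:
    """A replicated sweep over (J, q, L) combinations."""

    variant: str
    form: str
    J_values: Sequence[float]
    q_values: Sequence[float] = (1.0,)
    L_values: Sequence[int] = (40,)
    replicates: int = 20
    #: an integer number of MCS, or the rule "half_L_squared" (L**2 / 2)
    runtime_mcs: int | str = 800
    base_seed: int = 0
    early_exit: bool = False

    def __post_init__(self):
        if not (self.J_values and self.q_values and self.L_values):
            raise ValueError("J_values, q_values and L_values must be nonempty")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if isinstance(self.runtime_mcs, str) and self.runtime_mcs != HALF_L_SQUARED:
            raise ValueError(
                f"runtime_mcs must be an integer or {HALF_L_SQUARED!r}, "
                f"got {self.runtime_mcs!r}"
            )

    def runtime_for(self, L: int) -> int:
        if self.runtime_mcs == HALF_L_SQUARED:
            return max(1, L * L // 2)
        return int(self.runtime_mcs)


@dataclass(frozen=True)
class ObservableRecord:
    """Ensemble summary of one (J, q, L) sweep point."""

    variant: str
    form: str
    J: float
    q: float
    L: int
    R: int
    runtime_mcs: int
    mean_phi: float
    sem_phi: float | None
    mean_phi_staggered: float
    sem_phi_staggered: float | None


def summarize(values: Sequence[float]) -> tuple[float, float | None]:
    """Mean and standard error of the mean (unbiased sd / sqrt(R)).

    A single value has an undefined SEM, reported as None; an empty list is
    rejected.
    """
    values = list(values)
    if not values:
        raise ValueError("cannot summarize an empty list of values")
    mean = float(np.mean(values))
    if len(values) < 2:
        return mean, None
    sem = float(np.std(values, ddof=1)) / sqrt(len(values))
    return mean, sem


def _run_point(
    spec: SweepSpec, J: float, q: float, L: int
) -> ObservableRecord:
    runtime = spec.runtime_for(L)
    interaction = InteractionSpec(spec.form, float(J))
    phis, phis_st = [], []
    for r in range(spec.replicates):
        config = ModelConfig(
            variant=spec.variant,
            interaction=interaction,
            L=L,
            runtime_mcs=runtime,
            seed=spec.base_seed + r,
            q=q,
        )
        result = run_simulation(config, early_exit=spec.early_exit)
        phis.append(order_parameter(result.grid))
        phis_st.append(staggered_order_parameter(result.grid))
    mean_phi, sem_phi = summarize(phis)
    mean_st, sem_st = summarize(phis_st)
    return ObservableRecord(
        variant=spec.variant,
        form=spec.form,
        J=float(J),
        q=float(q),
        L=int(L),
        R=spec.replicates,
        runtime_mcs=runtime,
        mean_phi=mean_phi,
        sem_phi=sem_phi,
        mean_phi_staggered=mean_st,
        sem_phi_staggered=sem_st,
    )


def run_sweep(spec: SweepSpec) -> list[ObservableRecord]:
    """Run every (J, q, L) combination of the spec; deterministic in base_seed.

    Replicates across different combinations reuse the same derived seeds
    (common random numbers), which reduces the variance of differences
    along a parameter axis.
    """
    records = []
    for L, q, J in itertools.product(spec.L_values, spec.q_values, spec.J_values):
        records.append(_run_point(spec, J, q, L))
    return records


def run_scaling(spec: SweepSpec) -> list[ObservableRecord]:
    """Finite-size scaling sweep: >= 2 system sizes, runtime = L**2 / 2 each."""
    if len(set(spec.L_values)) < 2:
        raise ValueError("run_scaling needs at least two distinct L values")
    scaled = SweepSpec(
        variant=spec.variant,
        form=spec.form,
        J_values=spec.J_values,
        q_values=spec.q_values,
        L_values=sorted(set(spec.L_values)),
        replicates=spec.replicates,
        runtime_mcs=HALF_L_SQUARED,
        base_seed=spec.base_seed,
        early_exit=spec.early_exit,
    )
    return run_sweep(scaled)


def records_to_frame(records: Sequence[ObservableRecord]) -> pd.DataFrame:
    """Tabulate sweep records with the canonical column order."""
    return pd.DataFrame([r.__dict__ for r in records], columns=RECORD_COLUMNS)
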