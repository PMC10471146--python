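"""Markov cohort engine: health states, strategy graphs, cohort simulation.

A :class:`Strategy` is a named directed graph of :class:`HealthState` objects
whose edges draw their probabilities from a fixed value, a named parameter,
an age schedule, or the per-state residual (one residual edge per
non-absorbing state receives whatever mass the named edges leave over).
:func:`run_cohort` advances a probability-distributed cohort through the
graph in annual cycles, accumulating discounted costs and quality-adjusted
life years.

Reward timing: state membership rewards (utilities, per-cycle costs) accrue
at the end of each cycle, so the first accrual is discounted once; an
optional half-cycle correction weights the first and last rows by one half.
One-time entry costs (surgeries, complication management) are charged to the
flow entering the state in the cycle it enters, at that cycle's discount
factor; initial occupancy is charged undiscounted at cycle 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import TYPE_CHECKING, Mapping

import numpy as np
import yaml

from .parameters import AgeSchedule, ParameterSet

if TYPE_CHECKING:  # pragma: no cover
    from .costs import CostSchedule

PACKAGED_STRATEGY_FILES = {"AS": "strategy_as.yaml", "ES": "strategy_es.yaml"}

MASS_TOLERANCE = 1e-10


@dataclass(frozen=True)
class HealthState:
    """A labelled model state.

    ``utility_key`` and ``cycle_cost_key`` name entries in the parameter set
    and cost schedule (``None`` means zero, e.g. death); ``entry_cost_key``
    is a one-time cost charged on entering. ``permanent`` states persist
    until death; ``tunnel`` states are occupied for a single cycle.
    """

    name: str
    utility_key: str | None = None
    cycle_cost_key: str | None = None
    entry_cost_key: str | None = None
    absorbing: bool = False
    permanent: bool = False
    tunnel: bool = False


@dataclass(frozen=True)
class Transition:
    """One edge of the strategy graph.

    Exactly one of ``fixed``, ``param``, ``schedule``, ``residual``
    identifies the probability source.
    """

    frm: str
    to: str
    fixed: float | None = None
    param: str | None = None
    schedule: str | None = None
    residual: bool = False

    def __post_init__(self) -> None:
        sources = sum(
            (self.fixed is not None, self.param is not None,
             self.schedule is not None, self.residual)
        )
        if sources != 1:
            raise ValueError(
                f"transition {self.frm}->{self.to}: exactly one probability "
                f"source required, got {sources}"
            )


@dataclass
class Strategy:
    """A named state graph with initial occupancy and transition bindings."""

    name: str
    states: list[HealthState]
    transitions: list[Transition]
    initial_occupancy: dict[str, float]

    def __post_init__(self) -> None:
        names = [s.name for s in self.states]
        if len(set(names)) != len(names):
            raise ValueError(f"{self.name}: duplicate state names")
        self._index = {n: i for i, n in enumerate(names)}
        total = sum(self.initial_occupancy.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"{self.name}: initial occupancy sums to {total}, not 1")
        for t in self.transitions:
            for endpoint in (t.frm, t.to):
                if endpoint not in self._index:
                    raise ValueError(f"{self.name}: unknown state {endpoint!r} in transition")
        by_state: dict[str, list[Transition]] = {}
        for t in self.transitions:
            by_state.setdefault(t.frm, []).append(t)
        for state in self.states:
            outgoing = by_state.get(state.name, [])
            n_residual = sum(t.residual for t in outgoing)
            if state.absorbing:
                if outgoing:
                    raise ValueError(f"{self.name}: absorbing state {state.name} has edges")
            elif n_residual != 1:
                raise ValueError(
                    f"{self.name}: state {state.name} needs exactly one residual "
                    f"edge, has {n_residual}"
                )

    @property
    def state_names(self) -> list[str]:
        return [s.name for s in self.states]

    def state_index(self, name: str) -> int:
        return self._index[name]

    def initial_vector(self) -> np.ndarray:
        vec = np.zeros(len(self.states))
        for name, mass in self.initial_occupancy.items():
            vec[self._index[name]] = mass
        return vec

    def referenced_params(self) -> set[str]:
        return {t.param for t in self.transitions if t.param is not None}

    def referenced_utilities(self) -> set[str]:
        return {s.utility_key for s in self.states if s.utility_key is not None}


def load_strategy(source: str | Path) -> Strategy:
    """Load a strategy graph (packaged name ``"AS"``/``"ES"`` or a path)."""
    if isinstance(source, str) and source in PACKAGED_STRATEGY_FILES:
        text = (
            resources.files("ptmc_cea.data")
            .joinpath(PACKAGED_STRATEGY_FILES[source])
            .read_text()
        )
    else:
        text = Path(source).read_text()
    raw = yaml.safe_load(text)
    states = [
        HealthState(
            name=s["name"],
            utility_key=s.get("utility"),
            cycle_cost_key=s.get("cycle_cost"),
            entry_cost_key=s.get("entry_cost"),
            absorbing=bool(s.get("absorbing", False)),
            permanent=bool(s.get("permanent", False)),
            tunnel=bool(s.get("tunnel", False)),
        )
        for s in raw["states"]
    ]
    transitions = [
        Transition(
            frm=t["from"],
            to=t["to"],
            fixed=t.get("fixed"),
            param=t.get("param"),
            schedule=t.get("schedule"),
            residual=bool(t.get("residual", False)),
        )
        for t in raw["transitions"]
    ]
    return Strategy(
        name=raw["name"],
        states=states,
        transitions=transitions,
        initial_occupancy={k: float(v) for k, v in raw["initial_occupancy"].items()},
    )


def discount_factor(rate: float, cycle: int) -> float:
    """``(1 + rate)^-cycle``; 1 at cycle 0."""
    if rate < 0:
        raise ValueError(f"discount rate {rate} must be non-negative")
    return (1.0 + rate) ** (-cycle)


def build_transition_matrix(
    strategy: Strategy,
    params: ParameterSet,
    age: int,
    prob_values: Mapping[str, float] | None = None,
    background_mortality: AgeSchedule | None = None,
) -> np.ndarray:
    """Row-stochastic one-cycle transition matrix at a given age.

    ``prob_values`` overrides base-case probability points (used by the
    sensitivity analyses); age-schedule edges are looked up at ``age``.
    Raises if any state's named edges sum above 1 (negative residual).
    """
    n = len(strategy.states)
    matrix = np.zeros((n, n))
    named_sum = np.zeros(n)
    residual_target = np.full(n, -1, dtype=int)

    for t in strategy.transitions:
        i, j = strategy.state_index(t.frm), strategy.state_index(t.to)
        if t.residual:
            residual_target[i] = j
            continue
        if t.fixed is not None:
            p = float(t.fixed)
        elif t.param is not None:
            if prob_values is not None and t.param in prob_values:
                p = float(prob_values[t.param])
            else:
                p = params.probabilities[t.param].point
        else:
            assert t.schedule is not None
            p = params.schedule(t.schedule).lookup(age)
        if not 0.0 <= p <= 1.0:
            raise ValueError(
                f"{strategy.name}: edge {t.frm}->{t.to} probability {p} outside [0, 1]"
            )
        matrix[i, j] += p
        named_sum[i] += p

    for state in strategy.states:
        i = strategy.state_index(state.name)
        if state.absorbing:
            matrix[i, i] = 1.0
            continue
        residual = 1.0 - named_sum[i]
        if residual < -1e-12:
            raise ValueError(
                f"{strategy.name}: state {state.name!r} transition probabilities "
                f"sum to {named_sum[i]:.6f} > 1 (residual {residual:.2e})"
            )
        matrix[i, residual_target[i]] += max(residual, 0.0)

    if background_mortality is not None:
        death = strategy.state_index("death")
        m = background_mortality.lookup(age)
        for state in strategy.states:
            i = strategy.state_index(state.name)
            if state.absorbing:
                continue
            matrix[i] *= 1.0 - m
            matrix[i, death] += m

    return matrix


@dataclass
class CohortTrace:
    """Cycle-indexed occupancy matrix with discounted accumulators."""

    strategy_name: str
    state_names: list[str]
    start_age: int
    occupancy: np.ndarray  # (n_cycles + 1, n_states)
    per_cycle_qaly: np.ndarray  # discounted, length n_cycles + 1
    per_cycle_cost: np.ndarray  # discounted, length n_cycles + 1
    discounted_qaly: float
    discounted_cost: float
    discount_rate: float = field(default=0.0)

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def to_dataframe(self):
        """One row per cycle: age, per-state occupancy, discounted flows."""
        import pandas as pd

        df = pd.DataFrame(self.occupancy, columns=self.state_names)
        df.insert(0, "cycle", np.arange(self.n_cycles + 1))
        df.insert(1, "age", self.start_age + np.arange(self.n_cycles + 1))
        df["cycle_qaly"] = self.per_cycle_qaly
        df["cycle_cost"] = self.per_cycle_cost
        df["cum_qaly"] = np.cumsum(self.per_cycle_qaly)
        df["cum_cost"] = np.cumsum(self.per_cycle_cost)
        return df


def run_cohort(
    strategy: Strategy,
    params: ParameterSet,
    costs: "CostSchedule",
    start_age: int,
    n_cycles: int,
    discount: float | None = None,
    prob_values: Mapping[str, float] | None = None,
    util_values: Mapping[str, float] | None = None,
    half_cycle: bool = False,
    background_mortality: AgeSchedule | None = None,
) -> CohortTrace:
    """Run the annual-cycle cohort simulation for one strategy.

    Occupancy row 0 is the initial distribution; row ``k+1`` is row ``k``
    times the transition matrix at age ``start_age + k``. Discounted QALYs
    and costs follow the end-of-cycle accrual rule described in the module
    docstring. ``discount`` defaults to the parameter set's rate.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if discount is None:
        discount = params.discount_rate

    n_states = len(strategy.states)
    utilities = np.zeros(n_states)
    cycle_costs = np.zeros(n_states)
    entry_costs = np.zeros(n_states)
    for state in strategy.states:
        i = strategy.state_index(state.name)
        if state.utility_key is not None:
            if util_values is not None and state.utility_key in util_values:
                utilities[i] = float(util_values[state.utility_key])
            else:
                utilities[i] = params.utilities[state.utility_key].point
        if state.cycle_cost_key is not None:
            cycle_costs[i] = costs.cycle_cost(state.cycle_cost_key)
        if state.entry_cost_key is not None:
            entry_costs[i] = costs.event_cost(state.entry_cost_key)

    occupancy = np.empty((n_cycles + 1, n_states))
    occupancy[0] = strategy.initial_vector()
    per_cycle_qaly = np.zeros(n_cycles + 1)
    per_cycle_cost = np.zeros(n_cycles + 1)
    # initial occupancy enters its states at cycle 0: entry costs, undiscounted
    per_cycle_cost[0] = occupancy[0] @ entry_costs

    matrix_cache: dict[tuple, np.ndarray] = {}
    for k in range(n_cycles):
        age = start_age + k
        key = (
            params.growth_schedule.lookup(age),
            params.nodal_schedule.lookup(age),
            None if background_mortality is None else background_mortality.lookup(age),
        )
        matrix = matrix_cache.get(key)
        if matrix is None:
            matrix = build_transition_matrix(
                strategy, params, age, prob_values, background_mortality
            )
            matrix_cache[key] = matrix
        row = occupancy[k] @ matrix
        mass_err = abs(row.sum() - 1.0)
        if mass_err > MASS_TOLERANCE:
            raise RuntimeError(
                f"{strategy.name}: probability mass leak {mass_err:.2e} at cycle {k + 1}"
            )
        occupancy[k + 1] = row
        df = discount_factor(discount, k + 1)
        # flow entering each state this cycle (excluding those already there)
        inflow = row - occupancy[k] * matrix.diagonal()
        per_cycle_qaly[k + 1] = df * (row @ utilities)
        per_cycle_cost[k + 1] = df * (row @ cycle_costs + inflow @ entry_costs)

    if half_cycle:
        # half weight on the first and last rows; cycle-0 membership rewards
        # (normally skipped under end-of-cycle accrual) enter at half weight
        per_cycle_qaly[0] = 0.5 * (occupancy[0] @ utilities)
        per_cycle_cost[0] += 0.5 * (occupancy[0] @ cycle_costs)
        per_cycle_qaly[n_cycles] *= 0.5
        df_n = discount_factor(discount, n_cycles)
        per_cycle_cost[n_cycles] -= 0.5 * df_n * (occupancy[n_cycles] @ cycle_costs)

    return CohortTrace(
        strategy_name=strategy.name,
        state_names=strategy.state_names,
        start_age=start_age,
        occupancy=occupancy,
        per_cycle_qaly=per_cycle_qaly,
        per_cycle_cost=per_cycle_cost,
        discounted_qaly=float(per_cycle_qaly.sum()),
        discounted_cost=float(per_cycle_cost.sum()),
        discount_rate=discount,
    )
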