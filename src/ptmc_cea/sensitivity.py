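"""Deterministic (tornado) and probabilistic sensitivity analysis.

One-way deterministic analysis re-runs both strategies with a single input
pinned at the ends of its analysis range (published range where available,
otherwise ±10%; 1%-5% for the discount rate) and records the ICER spread.

Probabilistic analysis draws all uncertain inputs jointly and independently
— beta (method of moments from mean/SD) for probabilities and utilities,
normal truncated at zero for cost items — runs both strategies per draw with
the *same* parameter values, and summarizes the incremental cost/effect
cloud as CE-plane points, quadrant fractions, and a cost-effectiveness
acceptability curve (probability that the comparator has the higher net
monetary benefit at each willingness-to-pay threshold).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cea import CEResult, compute_icer, wtp_threshold
from .costs import CostSchedule
from .markov import Strategy, run_cohort
from .parameters import ParameterSet, dsa_range

#: default CEAC grid: 0 to three times per-capita GDP, 101 points
DEFAULT_WTP_GRID = tuple(np.linspace(0.0, wtp_threshold(), 101))


@dataclass
class ModelBundle:
    """Everything needed to evaluate both strategies at one scenario."""

    params: ParameterSet
    reference: Strategy  # early surgery
    comparator: Strategy  # active surveillance
    costs: CostSchedule
    start_age: int = 40
    n_cycles: int = 40
    discount: float | None = None
    half_cycle: bool = False

    def run_pair(
        self,
        prob_values=None,
        util_values=None,
        costs: CostSchedule | None = None,
        discount: float | None = None,
    ) -> tuple[tuple[float, float], tuple[float, float]]:
        """((reference cost, qaly), (comparator cost, qaly)) at given overrides."""
        costs = self.costs if costs is None else costs
        discount = self.discount if discount is None else discount
        out = []
        for strategy in (self.reference, self.comparator):
            trace = run_cohort(
                strategy,
                self.params,
                costs,
                start_age=self.start_age,
                n_cycles=self.n_cycles,
                discount=discount,
                prob_values=prob_values,
                util_values=util_values,
                half_cycle=self.half_cycle,
            )
            out.append((trace.discounted_cost, trace.discounted_qaly))
        return out[0], out[1]

    def base_case(self) -> CEResult:
        ref, comp = self.run_pair()
        return compute_icer(ref, comp, self.reference.name, self.comparator.name)


# ---------------------------------------------------------------------------
# deterministic one-way analysis


@dataclass(frozen=True)
class TornadoEntry:
    """ICER at the two ends of one parameter's analysis range."""

    parameter: str
    low: float
    high: float
    icer_low: float
    icer_high: float

    @property
    def spread(self) -> float:
        return abs(self.icer_high - self.icer_low)


def _resolve_parameter(bundle: ModelBundle, name: str) -> tuple[str, str]:
    """Map a possibly prefixed name to (category, bare name).

    Prefixes ``p:``, ``u:``, ``c:`` disambiguate probabilities, utilities and
    cost items whose bare names collide.
    """
    if name == "discount_rate":
        return "discount", name
    for prefix, category in (("p:", "prob"), ("u:", "util"), ("c:", "cost")):
        if name.startswith(prefix):
            return category, name[len(prefix):]
    hits = []
    if name in bundle.params.probabilities:
        hits.append("prob")
    if name in bundle.params.utilities:
        hits.append("util")
    if name in bundle.costs.items:
        hits.append("cost")
    if not hits:
        raise KeyError(f"unknown parameter {name!r}")
    if len(hits) > 1:
        raise KeyError(
            f"parameter name {name!r} is ambiguous ({'/'.join(hits)}); "
            "use a 'p:'/'u:'/'c:' prefix"
        )
    return hits[0], name


def one_way_dsa(
    bundle: ModelBundle,
    name: str,
    value_range: tuple[float, float] | None = None,
    fraction: float = 0.10,
) -> TornadoEntry:
    """Re-run both strategies with one input pinned at each end of its range."""
    category, bare = _resolve_parameter(bundle, name)
    if value_range is None:
        if category == "discount":
            value_range = dsa_range_for_discount()
        elif category == "prob":
            value_range = dsa_range(bundle.params.probabilities[bare], fraction)
        elif category == "util":
            value_range = dsa_range(bundle.params.utilities[bare], fraction)
        else:
            item = bundle.costs.items[bare]
            value_range = (item.value * (1 - fraction), item.value * (1 + fraction))

    icers = []
    for value in value_range:
        kwargs: dict = {}
        if category == "discount":
            kwargs["discount"] = value
        elif category == "prob":
            kwargs["prob_values"] = {bare: value}
        elif category == "util":
            kwargs["util_values"] = {bare: value}
        else:
            kwargs["costs"] = bundle.costs.with_values({bare: value})
        ref, comp = bundle.run_pair(**kwargs)
        icers.append(
            compute_icer(ref, comp, bundle.reference.name, bundle.comparator.name).icer
        )
    return TornadoEntry(
        parameter=name,
        low=float(value_range[0]),
        high=float(value_range[1]),
        icer_low=icers[0],
        icer_high=icers[1],
    )


def dsa_range_for_discount() -> tuple[float, float]:
    from .parameters import DISCOUNT_DSA_RANGE

    return DISCOUNT_DSA_RANGE


def tornado(bundle: ModelBundle, names: list[str] | None = None) -> list[TornadoEntry]:
    """One-way analysis over every model input, sorted by ICER spread.

    Default parameter list: every probability, every utility, every cost
    item, and the discount rate (qualified names avoid collisions).
    """
    if names is None:
        names = (
            [f"p:{n}" for n in bundle.params.probabilities]
            + [f"u:{n}" for n in bundle.params.utilities]
            + [f"c:{n}" for n in bundle.costs.items]
            + ["discount_rate"]
        )
    entries = [one_way_dsa(bundle, name) for name in names]
    return sorted(entries, key=lambda e: e.spread, reverse=True)


# ---------------------------------------------------------------------------
# probabilistic analysis


@dataclass
class PSAResult:
    """Monte Carlo CE-plane points and derived summaries.

    ``points`` holds one (delta cost ¥, delta effect QALY) row per iteration,
    comparator minus reference. The acceptability curve and the quadrant
    fractions are computed from these same points.
    """

    n_iterations: int
    seed: int
    points: np.ndarray  # (n, 2): delta_cost, delta_effect
    wtp_grid: tuple[float, ...] = DEFAULT_WTP_GRID
    ceac: list[tuple[float, float]] = field(init=False)
    quadrant_fractions: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        self.ceac = ceac_curve(self.points, list(self.wtp_grid))
        self.quadrant_fractions = quadrant_fractions(self.points)

    def first_quadrant_fraction(self) -> float:
        """Share of iterations where the comparator is costlier and more effective."""
        return self.quadrant_fractions["more_costly_more_effective"]


def quadrant_fractions(points: np.ndarray) -> dict[str, float]:
    """CE-plane quadrant shares (boundaries counted clockwise-inclusive)."""
    dc, de = points[:, 0], points[:, 1]
    n = len(points)
    q = {
        "more_costly_more_effective": np.mean((dc > 0) & (de > 0)),
        "more_costly_less_effective": np.mean((dc > 0) & (de <= 0)),
        "less_costly_less_effective": np.mean((dc <= 0) & (de <= 0)),
        "less_costly_more_effective": np.mean((dc <= 0) & (de > 0)),
    }
    assert abs(sum(q.values()) - 1.0) < 1e-12 or n == 0
    return {k: float(v) for k, v in q.items()}


def ceac_curve(points: np.ndarray, wtp_grid: list[float]) -> list[tuple[float, float]]:
    """Probability the comparator is cost-effective at each threshold.

    At threshold w the comparator wins when its net monetary benefit exceeds
    the reference's, i.e. ``w * delta_effect - delta_cost > 0``.
    """
    if len(points) == 0 or len(wtp_grid) == 0:
        raise ValueError("ceac_curve requires non-empty points and grid")
    dc, de = points[:, 0], points[:, 1]
    return [
        (float(w), float(np.mean(w * de - dc > 0.0)))
        for w in wtp_grid
    ]


def run_psa(
    bundle: ModelBundle,
    n_iterations: int = 1000,
    seed: int = 0,
    wtp_grid: tuple[float, ...] = DEFAULT_WTP_GRID,
) -> PSAResult:
    """Monte Carlo probabilistic sensitivity analysis.

    Per iteration, every uncertain probability and utility is drawn from its
    method-of-moments beta distribution, every cost item from a normal
    truncated at zero by resampling; both strategies run on the same draw.
    Reproducible given ``seed``.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    rng = np.random.default_rng(seed)

    # pre-draw all iterations per parameter, in sorted-name order for
    # reproducibility independent of dict insertion order
    prob_draws: dict[str, np.ndarray] = {}
    for name in sorted(bundle.params.probabilities):
        dist = bundle.params.probabilities[name]
        if dist.is_uncertain and dist.kind == "beta":
            a, b = dist.beta_shapes()  # infeasible moments raise here, at setup
            prob_draws[name] = rng.beta(a, b, size=n_iterations)
    util_draws: dict[str, np.ndarray] = {}
    for name in sorted(bundle.params.utilities):
        dist = bundle.params.utilities[name]
        if dist.is_uncertain and dist.kind == "beta":
            a, b = dist.beta_shapes()
            util_draws[name] = rng.beta(a, b, size=n_iterations)
    cost_draws: dict[str, np.ndarray] = {}
    for name in sorted(bundle.costs.items):
        item = bundle.costs.items[name]
        if item.sd > 0:
            draws = rng.normal(item.value, item.sd, size=n_iterations)
            while np.any(draws < 0):  # truncate at zero by resampling
                neg = draws < 0
                draws[neg] = rng.normal(item.value, item.sd, size=int(neg.sum()))
            cost_draws[name] = draws

    points = np.empty((n_iterations, 2))
    for i in range(n_iterations):
        prob_values = {k: v[i] for k, v in prob_draws.items()}
        util_values = {k: v[i] for k, v in util_draws.items()}
        costs_i = bundle.costs.with_values({k: v[i] for k, v in cost_draws.items()})
        ref, comp = bundle.run_pair(prob_values, util_values, costs_i)
        points[i, 0] = comp[0] - ref[0]
        points[i, 1] = comp[1] - ref[1]

    return PSAResult(
        n_iterations=n_iterations, seed=seed, points=points, wtp_grid=wtp_grid
    )
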