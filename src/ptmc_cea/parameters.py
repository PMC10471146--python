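"""Model inputs: transition probabilities, utilities, age-banded schedules.

Every numeric input of the decision model lives here: named parameter
distributions (point value for the base case, beta/normal moments for
probabilistic draws, a deterministic one-way analysis range), decade-banded
annual probabilities of primary tumor growth and nodal metastasis, the
rate <-> probability conversions used to harmonize multi-year incidences to
the 1-year model cycle, and the loader for the packaged parameter files.

Two packaged parameter files interpret the published decade-band progression
values differently: ``table1_verbatim`` takes them at face value as annual
probabilities, while ``text_canonical`` treats them as 10-year cumulative
incidences and converts them with ``r = -ln(1-p)/t`` (the conversion the
source text documents for the 40-59 band: 10-year 3.7% -> 0.38%/year).
The two readings differ by roughly a factor of ten; both are loadable and
the discrepancy is flagged in the load log.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator

import yaml

logger = logging.getLogger(__name__)

#: packaged parameter scenarios, by name
PACKAGED_PARAMETER_FILES = {
    "table1_verbatim": "parameters_table1_verbatim.yaml",
    "text_canonical": "parameters_text_canonical.yaml",
}

DEFAULT_DISCOUNT_RATE = 0.03
#: deterministic one-way range for the discount rate (fraction per year)
DISCOUNT_DSA_RANGE = (0.01, 0.05)

# utility rows that the packaged strategy graphs intentionally leave unbound
# (strategy-level values that are implausible or redundant as state weights)
_FLAGGED_UTILITIES = ("active_surveillance", "disease_progression")


# ---------------------------------------------------------------------------
# rate / probability conversions


def annual_rate_from_cumulative(p: float, t: float) -> float:
    """Annual event rate from a cumulative incidence over ``t`` years.

    Implements ``r = -ln(1 - p) / t`` under the usual constant-rate
    (exponential waiting time) assumption. For small ``p`` this is
    approximately ``p / t``.

    Parameters
    ----------
    p : cumulative incidence over the interval, in ``[0, 1)``.
    t : interval length in years, ``> 0``.
    """
    if not 0.0 <= p < 1.0:
        raise ValueError(f"cumulative probability p={p!r} must satisfy 0 <= p < 1")
    if t <= 0:
        raise ValueError(f"interval length t={t!r} must be positive")
    return -math.log1p(-p) / t


def prob_from_rate(r: float, t: float = 1.0) -> float:
    """Probability of at least one event in ``t`` years at constant rate ``r``.

    Inverse of :func:`annual_rate_from_cumulative`:
    ``prob_from_rate(annual_rate_from_cumulative(p, t), t) == p`` to machine
    precision.
    """
    if r < 0:
        raise ValueError(f"rate r={r!r} must be non-negative")
    if t <= 0:
        raise ValueError(f"interval length t={t!r} must be positive")
    return -math.expm1(-r * t)


def beta_params_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Method-of-moments beta shape parameters for a given mean and SD.

    With ``nu = mean (1 - mean) / sd^2 - 1``, returns
    ``alpha = mean * nu`` and ``beta = (1 - mean) * nu``; a
    ``Beta(alpha, beta)`` draw has the requested first two moments.
    Requires ``sd^2 < mean (1 - mean)``.
    """
    if not 0.0 < mean < 1.0:
        raise ValueError(f"mean={mean!r} must lie strictly in (0, 1)")
    if sd <= 0:
        raise ValueError(f"sd={sd!r} must be positive")
    var = sd * sd
    feasible = mean * (1.0 - mean)
    if var >= feasible:
        raise ValueError(
            f"variance infeasible for beta: sd^2={var:.6g} >= mean(1-mean)={feasible:.6g}"
        )
    nu = feasible / var - 1.0
    return mean * nu, (1.0 - mean) * nu


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class ParameterDistribution:
    """A model input: base-case point value plus uncertainty description.

    ``kind`` is one of ``beta`` (probabilities and utilities), ``normal``
    (costs) or ``fixed``; ``mean``/``sd`` parameterize the probabilistic
    draw, ``dsa_low``/``dsa_high`` bound the deterministic one-way analysis.
    """

    name: str
    kind: str
    point: float
    mean: float | None = None
    sd: float | None = None
    dsa_low: float | None = None
    dsa_high: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("beta", "normal", "fixed"):
            raise ValueError(f"{self.name}: unknown distribution kind {self.kind!r}")
        if self.kind == "beta":
            if not 0.0 <= self.point <= 1.0:
                raise ValueError(f"{self.name}: beta point {self.point!r} outside [0, 1]")
            if self.mean is not None:
                if not 0.0 < self.mean < 1.0:
                    raise ValueError(f"{self.name}: beta mean {self.mean!r} outside (0, 1)")
                if self.sd:
                    if self.sd < 0:
                        raise ValueError(f"{self.name}: sd must be >= 0")
                    beta_params_from_moments(self.mean, self.sd)  # feasibility check
        if self.dsa_low is not None and self.dsa_high is not None:
            if not self.dsa_low <= self.point <= self.dsa_high:
                raise ValueError(
                    f"{self.name}: point {self.point} outside analysis range "
                    f"[{self.dsa_low}, {self.dsa_high}]"
                )

    @property
    def is_uncertain(self) -> bool:
        return self.kind != "fixed" and self.sd is not None and self.sd > 0

    def beta_shapes(self) -> tuple[float, float]:
        if self.kind != "beta" or not self.is_uncertain:
            raise ValueError(f"{self.name}: no beta distribution defined")
        assert self.mean is not None and self.sd is not None
        return beta_params_from_moments(self.mean, self.sd)


def dsa_range(
    dist: ParameterDistribution,
    fraction: float = 0.10,
    domain: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Deterministic one-way analysis range for a parameter.

    The explicit ``dsa_low``/``dsa_high`` bounds (the published analysis
    range) are authoritative when present; otherwise the range is
    ``point * (1 - fraction, 1 + fraction)`` clipped to the parameter's legal
    domain (``[0, 1]`` for beta-kind parameters, non-negative for costs).
    The discount rate is special-cased to the published 1%-5% band.
    """
    if dist.name == "discount_rate":
        return DISCOUNT_DSA_RANGE
    if dist.dsa_low is not None and dist.dsa_high is not None:
        return (dist.dsa_low, dist.dsa_high)
    low = dist.point * (1.0 - fraction)
    high = dist.point * (1.0 + fraction)
    if domain is None:
        domain = (0.0, 1.0) if dist.kind == "beta" else (0.0, math.inf)
    return (max(low, domain[0]), min(high, domain[1]))


@dataclass(frozen=True)
class AgeSchedule:
    """Ordered, contiguous decade bands of annual probabilities by age.

    ``bands`` is a tuple of ``(age_low, age_high, annual_prob)`` with
    inclusive integer bounds. ``extend_to`` carries the last band forward so
    that cohorts simulated past the covered ages reuse the oldest band's
    probability.
    """

    name: str
    bands: tuple[tuple[int, int, float], ...]

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError(f"{self.name}: empty schedule")
        prev_high = None
        for low, high, prob in self.bands:
            if low > high:
                raise ValueError(f"{self.name}: band {low}-{high} reversed")
            if prev_high is not None and low != prev_high + 1:
                raise ValueError(f"{self.name}: bands not contiguous at age {low}")
            if not 0.0 <= prob <= 1.0:
                raise ValueError(f"{self.name}: probability {prob} outside [0, 1]")
            prev_high = high

    @property
    def age_min(self) -> int:
        return self.bands[0][0]

    @property
    def age_max(self) -> int:
        return self.bands[-1][1]

    def lookup(self, age: int) -> float:
        """Annual probability for an integer age (inclusive band bounds)."""
        for low, high, prob in self.bands:
            if low <= age <= high:
                return prob
        raise ValueError(
            f"{self.name}: age {age} outside covered range "
            f"[{self.age_min}, {self.age_max}]; extend the schedule "
            f"(e.g. schedule.extend_to({age}))"
        )

    def extend_to(self, age: int) -> "AgeSchedule":
        """Return a schedule extended to ``age`` by carrying the last band forward."""
        if age <= self.age_max:
            return self
        last = self.bands[-1]
        return AgeSchedule(self.name, self.bands + ((last[1] + 1, age, last[2]),))


def lookup_age_prob(schedule: AgeSchedule, age: int) -> float:
    """Annual probability from an age schedule (thin functional wrapper)."""
    return schedule.lookup(age)


@dataclass
class ParameterSet:
    """The complete numeric input set of the model.

    Probabilities and utilities are named :class:`ParameterDistribution`
    collections; the two age schedules drive the age-dependent progression
    probabilities; ``warnings`` is the load log of flagged oddities.
    """

    name: str
    probabilities: dict[str, ParameterDistribution]
    utilities: dict[str, ParameterDistribution]
    growth_schedule: AgeSchedule
    nodal_schedule: AgeSchedule
    discount_rate: float = DEFAULT_DISCOUNT_RATE
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.discount_rate <= 0.05:
            raise ValueError(f"discount_rate {self.discount_rate} outside [0, 0.05]")
        for dist in self.iter_distributions():
            if not 0.0 <= dist.point <= 1.0:
                raise ValueError(f"{dist.name}: point {dist.point} outside [0, 1]")

    def iter_distributions(self) -> Iterator[ParameterDistribution]:
        yield from self.probabilities.values()
        yield from self.utilities.values()

    def schedule(self, name: str) -> AgeSchedule:
        if name == "nodule_growth":
            return self.growth_schedule
        if name == "nodal_metastasis":
            return self.nodal_schedule
        raise KeyError(f"unknown age schedule {name!r}")

    def point_values(self) -> dict[str, float]:
        """Base-case value of every probability and utility, by name.

        Probability and utility namespaces are disjoint except where a row
        name legitimately appears in both (e.g. the unilateral-RLN-injury
        row); the two namespaces are therefore kept prefixed.
        """
        values = {f"p:{k}": d.point for k, d in self.probabilities.items()}
        values.update({f"u:{k}": d.point for k, d in self.utilities.items()})
        return values


# ---------------------------------------------------------------------------
# loading


def _parse_distribution(name: str, spec: dict, kind_default: str = "beta") -> ParameterDistribution:
    kind = str(spec.get("distribution", kind_default)).lower()
    if kind in ("-", "none", "fixed"):
        kind = "fixed"
    rng = spec.get("dsa_range")
    return ParameterDistribution(
        name=name,
        kind=kind,
        point=float(spec["point"]),
        mean=None if spec.get("mean") is None else float(spec["mean"]),
        sd=None if spec.get("sd") is None else float(spec["sd"]),
        dsa_low=None if rng is None else float(rng[0]),
        dsa_high=None if rng is None else float(rng[1]),
    )


def _parse_schedule(name: str, spec: dict, warnings: list[str]) -> AgeSchedule:
    interpretation = spec.get("interpretation", "annual")
    bands = []
    for band in spec["bands"]:
        low, high = (int(a) for a in band["ages"])
        value = float(band["value"])
        if interpretation == "cumulative_10yr":
            value = prob_from_rate(annual_rate_from_cumulative(value, 10.0), 1.0)
        elif interpretation != "annual":
            raise ValueError(f"{name}: unknown interpretation {interpretation!r}")
        bands.append((low, high, value))
    if interpretation == "cumulative_10yr":
        warnings.append(
            f"schedule {name!r}: decade-band values interpreted as 10-year cumulative "
            "incidences and converted to annual probabilities via r = -ln(1-p)/t"
        )
    return AgeSchedule(name, tuple(bands))


def load_parameters(source: str | Path, extend_age: int = 120) -> ParameterSet:
    """Load a parameter file (packaged scenario name or a filesystem path).

    Validates every invariant, extends the age schedules to ``extend_age``
    by carrying the oldest band forward, and records load-time flags
    (unit-interpretation conversions, implausible utilities, moment
    mismatches) in ``ParameterSet.warnings``.
    """
    if isinstance(source, str) and source in PACKAGED_PARAMETER_FILES:
        text = (
            resources.files("ptmc_cea.data")
            .joinpath(PACKAGED_PARAMETER_FILES[source])
            .read_text()
        )
    else:
        text = Path(source).read_text()
    raw = yaml.safe_load(text)

    warnings: list[str] = []
    try:
        probabilities = {
            name: _parse_distribution(name, spec) for name, spec in raw["probabilities"].items()
        }
        utilities = {
            name: _parse_distribution(name, spec) for name, spec in raw["utilities"].items()
        }
        schedules = {
            name: _parse_schedule(name, spec, warnings)
            for name, spec in raw["age_schedules"].items()
        }
    except (KeyError, TypeError) as exc:
        raise ValueError(f"malformed parameter file {source!r}: {exc}") from exc
    if set(schedules) != {"nodule_growth", "nodal_metastasis"}:
        raise ValueError(
            f"parameter file must define age_schedules nodule_growth and "
            f"nodal_metastasis, got {sorted(schedules)}"
        )

    for name in _FLAGGED_UTILITIES:
        if name in utilities:
            warnings.append(
                f"utility {name!r} = {utilities[name].point} loaded verbatim; "
                "strategy-level value, not bound to a packaged health state"
            )
    for dist in utilities.values():
        if dist.mean is not None and abs(dist.mean - dist.point) > 1e-9:
            warnings.append(
                f"utility {dist.name!r}: point {dist.point} differs from "
                f"distribution mean {dist.mean} (loaded verbatim)"
            )

    params = ParameterSet(
        name=raw.get("name", str(source)),
        probabilities=probabilities,
        utilities=utilities,
        growth_schedule=schedules["nodule_growth"].extend_to(extend_age),
        nodal_schedule=schedules["nodal_metastasis"].extend_to(extend_age),
        discount_rate=float(raw.get("discount_rate", DEFAULT_DISCOUNT_RATE)),
        warnings=warnings,
    )
    for message in warnings:
        logger.info("parameter load [%s]: %s", params.name, message)
    return params
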