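"""Synthetic direct-medical-cost schedule and its calibration.

The study's actual hospital cost data are not published, so this module
stands in with a fully itemized SYNTHETIC schedule of plausible Chinese
tertiary-hospital charges (¥): one-time surgical event costs and recurring
surveillance / follow-up items composed into per-cycle costs. Nothing here
claims to be a hospital's actual prices.

Two calibration groups — ``surgical`` (event costs) and ``surveillance``
(recurring items) — each carry a scale factor. Discounted lifetime cost is
exactly linear and homogeneous in these factors (probabilities held fixed),
so :func:`calibrate_costs` can match the two published lifetime totals by
solving a 2x2 linear system built from three model evaluations, clamping to
bounds and verifying the solution by a rerun.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import TYPE_CHECKING, Callable, Mapping

import numpy as np
import yaml

if TYPE_CHECKING:  # pragma: no cover
    from .sensitivity import ModelBundle

PACKAGED_COST_FILE = "costs_synthetic_default.yaml"

GROUPS = ("surgical", "surveillance")


@dataclass(frozen=True)
class CostItem:
    """One itemized charge (¥) with a plausibility range and PSA SD."""

    name: str
    value: float
    low: float
    high: float
    group: str
    sd: float

    def __post_init__(self) -> None:
        if self.value < 0 or self.low < 0:
            raise ValueError(f"{self.name}: costs must be non-negative")
        if not self.low <= self.value <= self.high:
            raise ValueError(f"{self.name}: value {self.value} outside range [{self.low}, {self.high}]")
        if self.group not in GROUPS:
            raise ValueError(f"{self.name}: unknown group {self.group!r}")


@dataclass(frozen=True)
class CostSchedule:
    """Itemized event and per-cycle costs with composition rules.

    ``items`` maps item name -> :class:`CostItem`; ``compositions`` maps a
    per-cycle cost key to ``(item, multiplier)`` terms. Event costs are
    looked up directly by item name.
    """

    name: str
    items: dict[str, CostItem]
    compositions: dict[str, tuple[tuple[str, float], ...]]
    currency: str = "CNY"
    price_year: str = "2021"

    def __post_init__(self) -> None:
        for key, terms in self.compositions.items():
            for item, times in terms:
                if item not in self.items:
                    raise ValueError(f"composition {key!r} references unknown item {item!r}")
                if times < 0:
                    raise ValueError(f"composition {key!r}: negative multiplier for {item!r}")

    def event_cost(self, key: str) -> float:
        return self.items[key].value

    def cycle_cost(self, key: str) -> float:
        if key in self.compositions:
            return sum(self.items[item].value * times for item, times in self.compositions[key])
        return self.items[key].value

    def item_values(self) -> dict[str, float]:
        return {name: item.value for name, item in self.items.items()}

    def with_values(self, values: Mapping[str, float]) -> "CostSchedule":
        """Copy of the schedule with some item values replaced (range unchecked)."""
        items = {}
        for name, item in self.items.items():
            if name in values:
                v = float(values[name])
                if v < 0:
                    raise ValueError(f"{name}: costs must be non-negative")
                items[name] = dataclasses.replace(
                    item, value=v, low=min(item.low, v), high=max(item.high, v)
                )
            else:
                items[name] = item
        return dataclasses.replace(self, items=items)

    def scaled(self, surgical: float = 1.0, surveillance: float = 1.0) -> "CostSchedule":
        """Copy with every item multiplied by its group's factor."""
        factors = {"surgical": surgical, "surveillance": surveillance}
        return self.with_values(
            {name: item.value * factors[item.group] for name, item in self.items.items()}
        )


def load_cost_schedule(source: str | Path | None = None) -> CostSchedule:
    """Load a cost schedule file; default is the packaged synthetic schedule."""
    if source is None:
        text = resources.files("ptmc_cea.data").joinpath(PACKAGED_COST_FILE).read_text()
    else:
        text = Path(source).read_text()
    raw = yaml.safe_load(text)
    sd_fraction = float(raw.get("sd_fraction", 0.10))
    items = {
        name: CostItem(
            name=name,
            value=float(spec["value"]),
            low=float(spec["range"][0]),
            high=float(spec["range"][1]),
            group=spec["group"],
            sd=float(spec.get("sd", sd_fraction * float(spec["value"]))),
        )
        for name, spec in raw["items"].items()
    }
    compositions = {
        key: tuple((term["item"], float(term.get("times", 1))) for term in terms)
        for key, terms in raw.get("compositions", {}).items()
    }
    return CostSchedule(
        name=raw.get("name", str(source)),
        items=items,
        compositions=compositions,
        currency=raw.get("currency", "CNY"),
        price_year=str(raw.get("price_year", "2021")),
    )


def generate_cost_schedule(seed: int, scale: float = 1.0) -> CostSchedule:
    """Draw an itemized schedule from the packaged plausibility ranges.

    Each item is sampled uniformly from its documented range, then multiplied
    by ``scale``; deterministic under ``seed``.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    base = load_cost_schedule()
    rng = np.random.default_rng(seed)
    values = {
        name: scale * rng.uniform(item.low, item.high)
        for name, item in sorted(base.items.items())
    }
    return base.with_values(values)


@dataclass
class CalibrationResult:
    """Outcome of the two-factor cost calibration."""

    schedule: CostSchedule
    surgical_factor: float
    surveillance_factor: float
    achieved: tuple[float, float]  # (ES total, AS total), ¥
    targets: tuple[float, float]
    converged: bool

    @property
    def residuals(self) -> tuple[float, float]:
        return (self.achieved[0] - self.targets[0], self.achieved[1] - self.targets[1])


def calibrate_costs(
    schedule: CostSchedule,
    targets: tuple[float, float],
    evaluate: Callable[[CostSchedule], tuple[float, float]],
    rel_tol: float = 0.01,
    bounds: tuple[float, float] = (1e-3, 1e3),
) -> CalibrationResult:
    """Scale the schedule so base-case lifetime totals match ``targets``.

    ``evaluate(schedule) -> (ES total, AS total)`` runs the model at base-case
    parameters. Lifetime cost is linear and homogeneous in the two group
    factors, so the factors solve a 2x2 linear system assembled from
    evaluations at factor pairs (1,0) and (0,1); out-of-bounds solutions are
    clamped and the result flagged non-converged if the verifying rerun
    misses either target by more than ``rel_tol`` relatively.
    """
    if min(targets) <= 0:
        raise ValueError("calibration targets must be positive")
    col_surg = np.array(evaluate(schedule.scaled(1.0, 0.0)))
    col_surv = np.array(evaluate(schedule.scaled(0.0, 1.0)))
    design = np.column_stack([col_surg, col_surv])
    try:
        factors = np.linalg.solve(design, np.asarray(targets, dtype=float))
    except np.linalg.LinAlgError:
        factors = np.linalg.lstsq(design, np.asarray(targets, dtype=float), rcond=None)[0]
    factors = np.clip(factors, bounds[0], bounds[1])
    calibrated = schedule.scaled(float(factors[0]), float(factors[1]))
    achieved = tuple(float(v) for v in evaluate(calibrated))
    converged = all(
        abs(a - t) <= rel_tol * t for a, t in zip(achieved, targets)
    )
    return CalibrationResult(
        schedule=calibrated,
        surgical_factor=float(factors[0]),
        surveillance_factor=float(factors[1]),
        achieved=achieved,  # type: ignore[arg-type]
        targets=(float(targets[0]), float(targets[1])),
        converged=converged,
    )
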