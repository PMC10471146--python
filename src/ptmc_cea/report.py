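"""Scenario configuration, study driver, and file reports.

A :class:`Scenario` pins one comparison (start age, horizon, discount) of the
two packaged strategies; :func:`run_scenario` produces the published-table
style report rows plus full cohort traces, and :func:`run_full_study`
executes the whole reproduction — cost calibration, the three age scenarios,
the one-way tornado analysis over every input, and the Monte Carlo
probabilistic analysis — writing CSV/JSON artifacts and a manifest with
checksums so reruns are verifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cea import CEResult, wtp_threshold
from .costs import CalibrationResult, CostSchedule, calibrate_costs, load_cost_schedule
from .markov import CohortTrace, Strategy, load_strategy
from .parameters import ParameterSet, load_parameters
from .sensitivity import ModelBundle, PSAResult, run_psa, tornado

logger = logging.getLogger(__name__)

PACKAGED_CONFIG = "config_study.yaml"
#: the cohort is followed to this age in the packaged scenarios
HORIZON_AGE = 80

#: published base-case lifetime totals (¥) used as calibration targets
PUBLISHED_COST_TARGETS = {"ES": 53_461.0, "AS": 74_198.0}

#: published comparison table (cost ¥, effect QALY) by start age — inputs for
#: arithmetic-identity checks and calibration, not model outputs
PUBLISHED_TABLE = {
    20: {"ES": (53_450.0, 5.2), "AS": (137_744.0, 29.8)},
    40: {"ES": (53_461.0, 5.2), "AS": (74_198.0, 25.8)},
    60: {"ES": (53_449.0, 5.2), "AS": (38_127.0, 16.9)},
}


@dataclass
class Scenario:
    """One model comparison: start age, horizon, discount, input sources."""

    start_age: int
    n_cycles: int | None = None
    discount: float | None = None
    parameters: str = "table1_verbatim"
    reference_strategy: str = "ES"
    comparator_strategy: str = "AS"
    costs: str | None = None
    seed: int = 0
    half_cycle: bool = False

    def __post_init__(self) -> None:
        if self.n_cycles is None:
            self.n_cycles = HORIZON_AGE - self.start_age
        if self.n_cycles < 1:
            raise ValueError(f"scenario at start age {self.start_age}: horizon empty")


@dataclass
class ScenarioResult:
    scenario: Scenario
    ce: CEResult
    traces: dict[str, CohortTrace]
    table: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        self.table = pd.DataFrame(self.ce.to_rows())


def _bundle_for(scenario: Scenario, costs: CostSchedule | None = None) -> ModelBundle:
    params = load_parameters(scenario.parameters)
    return ModelBundle(
        params=params,
        reference=load_strategy(scenario.reference_strategy),
        comparator=load_strategy(scenario.comparator_strategy),
        costs=costs if costs is not None else load_cost_schedule(scenario.costs),
        start_age=scenario.start_age,
        n_cycles=scenario.n_cycles,
        discount=scenario.discount,
        half_cycle=scenario.half_cycle,
    )


def run_scenario(
    scenario: Scenario,
    costs: CostSchedule | None = None,
    out_dir: str | Path | None = None,
) -> ScenarioResult:
    """Run both strategies for one scenario; optionally write report files."""
    from .markov import run_cohort

    bundle = _bundle_for(scenario, costs)
    traces = {}
    totals = {}
    for strategy in (bundle.reference, bundle.comparator):
        trace = run_cohort(
            strategy,
            bundle.params,
            bundle.costs,
            start_age=bundle.start_age,
            n_cycles=bundle.n_cycles,
            discount=bundle.discount,
            half_cycle=bundle.half_cycle,
        )
        traces[strategy.name] = trace
        totals[strategy.name] = (trace.discounted_cost, trace.discounted_qaly)
    from .cea import compute_icer

    ce = compute_icer(
        totals[bundle.reference.name],
        totals[bundle.comparator.name],
        bundle.reference.name,
        bundle.comparator.name,
    )
    result = ScenarioResult(scenario=scenario, ce=ce, traces=traces)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tag = f"age{scenario.start_age}"
        _write_csv(result.table, out / f"report_{tag}.csv")
        for name, trace in traces.items():
            _write_csv(trace.to_dataframe(), out / f"trace_{tag}_{name}.csv")
    return result


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def _sha256(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()


def load_config(source: str | Path | None = None) -> dict:
    """Load a study config file; default is the packaged study."""
    if source is None:
        text = resources.files("ptmc_cea.data").joinpath(PACKAGED_CONFIG).read_text()
    else:
        text = Path(source).read_text()
    return yaml.safe_load(text)


def run_full_study(
    config: dict | str | Path | None = None,
    out_dir: str | Path = "outputs",
    seed: int | None = None,
) -> dict:
    """One-shot reproduction: calibration, 3 scenarios, tornado, PSA, CEAC.

    Returns (and writes) a manifest listing every artifact with its checksum,
    the seeds used, input warnings, and the calibration outcome. ``seed``
    overrides the config's PSA seed.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    param_source = config.get("parameters", "table1_verbatim")
    ref_name = config.get("strategies", {}).get("reference", "ES")
    comp_name = config.get("strategies", {}).get("comparator", "AS")
    discount = config.get("discount")
    half_cycle = bool(config.get("half_cycle", False))
    psa_cfg = config.get("psa", {})
    psa_seed = int(psa_cfg.get("seed", 0)) if seed is None else int(seed)
    base_age = int(config.get("base_start_age", 40))

    params = load_parameters(param_source)
    costs = load_cost_schedule(config.get("costs"))

    manifest: dict = {
        "version": __version__,
        "config": config,
        "seed": psa_seed,
        "parameter_warnings": list(params.warnings),
        "outputs": {},
        "failures": [],
    }

    # --- cost calibration at the base scenario -----------------------------
    calibration: CalibrationResult | None = None
    cal_cfg = config.get("calibration") or {}
    if cal_cfg.get("targets"):
        targets = (float(cal_cfg["targets"][ref_name]), float(cal_cfg["targets"][comp_name]))
        base_bundle = ModelBundle(
            params,
            load_strategy(ref_name),
            load_strategy(comp_name),
            costs,
            start_age=base_age,
            n_cycles=HORIZON_AGE - base_age,
            discount=discount,
            half_cycle=half_cycle,
        )
        calibration = calibrate_costs(
            costs,
            targets,
            lambda c: tuple(x[0] for x in base_bundle.run_pair(costs=c)),
            rel_tol=float(cal_cfg.get("rel_tol", 0.01)),
        )
        if not calibration.converged:
            manifest["failures"].append(
                f"cost calibration not converged: achieved {calibration.achieved} "
                f"vs targets {calibration.targets}"
            )
        costs = calibration.schedule
        manifest["calibration"] = {
            "surgical_factor": calibration.surgical_factor,
            "surveillance_factor": calibration.surveillance_factor,
            "achieved": calibration.achieved,
            "targets": calibration.targets,
            "converged": calibration.converged,
        }

    # --- age scenarios ------------------------------------------------------
    for sc_cfg in config.get("scenarios", [{"start_age": base_age}]):
        start_age = int(sc_cfg["start_age"])
        scenario = Scenario(
            start_age=start_age,
            n_cycles=sc_cfg.get("n_cycles"),
            discount=discount,
            parameters=param_source,
            reference_strategy=ref_name,
            comparator_strategy=comp_name,
            seed=psa_seed,
            half_cycle=half_cycle,
        )
        try:
            run_scenario(scenario, costs=costs, out_dir=out)
            for stem in (
                [f"report_age{start_age}"]
                + [f"trace_age{start_age}_{n}" for n in (ref_name, comp_name)]
            ):
                path = out / f"{stem}.csv"
                manifest["outputs"][path.name] = _sha256(path.read_text())
        except Exception as exc:  # record partial failures, keep going
            logger.exception("scenario age %s failed", start_age)
            manifest["failures"].append(f"scenario age {start_age}: {exc}")

    # --- sensitivity analyses on the base scenario --------------------------
    bundle = ModelBundle(
        params,
        load_strategy(ref_name),
        load_strategy(comp_name),
        costs,
        start_age=base_age,
        n_cycles=HORIZON_AGE - base_age,
        discount=discount,
        half_cycle=half_cycle,
    )
    try:
        entries = tornado(bundle)
        tornado_df = pd.DataFrame(
            [
                {
                    "parameter": e.parameter,
                    "low": e.low,
                    "high": e.high,
                    "icer_low": e.icer_low,
                    "icer_high": e.icer_high,
                    "spread": e.spread,
                }
                for e in entries
            ]
        )
        _write_csv(tornado_df, out / "tornado.csv")
        manifest["outputs"]["tornado.csv"] = _sha256((out / "tornado.csv").read_text())
    except Exception as exc:
        logger.exception("tornado analysis failed")
        manifest["failures"].append(f"tornado: {exc}")

    try:
        psa = run_psa(bundle, n_iterations=int(psa_cfg.get("iterations", 1000)), seed=psa_seed)
        psa_df = pd.DataFrame(psa.points, columns=["delta_cost", "delta_effect"])
        psa_df.insert(0, "iteration", range(len(psa_df)))
        _write_csv(psa_df, out / "psa_points.csv")
        ceac_df = pd.DataFrame(psa.ceac, columns=["wtp", "probability_cost_effective"])
        _write_csv(ceac_df, out / "ceac.csv")
        manifest["outputs"]["psa_points.csv"] = _sha256((out / "psa_points.csv").read_text())
        manifest["outputs"]["ceac.csv"] = _sha256((out / "ceac.csv").read_text())
        manifest["psa_quadrants"] = psa.quadrant_fractions
    except Exception as exc:
        logger.exception("probabilistic analysis failed")
        manifest["failures"].append(f"psa: {exc}")

    manifest["wtp_threshold"] = wtp_threshold(
        float(config.get("wtp", {}).get("gdp_per_capita", 80976)),
        float(config.get("wtp", {}).get("multiplier", 3)),
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return manifest
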