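# ptmc-cea

A Markov cohort cost-effectiveness model comparing **active surveillance
(AS)** with **early surgery (ES, upfront hemithyroidectomy)** for low-risk
papillary thyroid microcarcinoma (PTMC) from a Chinese healthcare payer
perspective — for health economists and methodologists who want a tested,
scriptable re-implementation of this comparison rather than a spreadsheet
or a proprietary decision-tree tool.

A probability-distributed cohort of 40-year-old women (subgroups: 20 and
60) advances through strategy-specific health-state graphs in 1-year
cycles to age 80. Surgery states are one-cycle tunnels splitting into
perioperative death and permanent/temporary complication states; two
decade-banded schedules make tumor-growth and nodal-metastasis
probabilities age-dependent. Costs (¥) and QALYs are discounted at 3%/year
with end-of-cycle accrual, and the strategies are compared by

- **ICER** = ΔC/ΔE (¥ per QALY gained, AS vs ES),
- **CER** = C/E per strategy, and
- **NMB(λ)** = λ·E − C at a willingness-to-pay λ = 3 × per-capita GDP
  = ¥242,928/QALY,

with one-way (tornado) and probabilistic (1,000-draw Monte Carlo, CE
plane, acceptability curve) sensitivity analyses. Multi-year incidences
are converted to the annual cycle with r = −ln(1−p)/t.

The study's itemized hospital costs are unpublished, so the package ships
a clearly labelled **synthetic** cost schedule (itemized surveillance
visits, surgeries, complication management) with a two-factor calibration
that matches the published base-case lifetime totals exactly; see
`docs/methods.md` for what that does and does not imply.

## Worked example

```python
from ptmc_cea import (ModelBundle, calibrate_costs, load_cost_schedule,
                      load_parameters, load_strategy, run_psa)

params = load_parameters("table1_verbatim")   # or "text_canonical"
bundle = ModelBundle(params, load_strategy("ES"), load_strategy("AS"),
                     load_cost_schedule(), start_age=40, n_cycles=40)

# scale the synthetic cost schedule to the published lifetime totals
cal = calibrate_costs(bundle.costs, (53_461, 74_198),
                      lambda c: tuple(x[0] for x in bundle.run_pair(costs=c)))
bundle.costs = cal.schedule
print(f"factors: surgical {cal.surgical_factor:.3f}, "
      f"surveillance {cal.surveillance_factor:.3f}")

ce = bundle.base_case()
print(f"ES: ¥{ce.reference[0]:,.0f} / {ce.reference[1]:.1f} QALY")
print(f"AS: ¥{ce.comparator[0]:,.0f} / {ce.comparator[1]:.1f} QALY")
print(f"ICER: ¥{ce.icer:,.0f}/QALY")

psa = run_psa(bundle, n_iterations=1000, seed=1)
print(f"first quadrant: {100 * psa.first_quadrant_fraction():.1f}%")
```

prints

```
factors: surgical 0.789, surveillance 1.170
ES: ¥53,461 / 17.1 QALY
AS: ¥74,198 / 21.2 QALY
ICER: ¥5,079/QALY
first quadrant: 99.4%
```

So after calibration the two arms hit the published cost totals; active
surveillance gains ≈4.1 QALYs at an extra ¥20,737, an ICER of ≈¥5,100 per
QALY — far below the ¥242,928 threshold — and ~99% of probabilistic draws
land in the costlier-but-more-effective quadrant, i.e. surgery is never
the cost-effective option at conventional thresholds. (The published QALY
totals themselves are not reproducible from the printed inputs;
`docs/methods.md` discusses why the package reports its own.)

The same analyses are available from the shell:

```sh
ptmc-cea run --start-age 60          # one scenario, comparison table
ptmc-cea study --seed 1 --out out/   # calibration + 3 scenarios + DSA + PSA
ptmc-cea dsa                         # tornado over every input
ptmc-cea psa --iterations 1000 --seed 1
ptmc-cea calibrate-costs
ptmc-cea validate                    # load-and-check inputs, print flags
```

## Layout

| path | contents |
| --- | --- |
| `src/ptmc_cea/parameters.py` | input distributions, age schedules, rate conversions, loaders |
| `src/ptmc_cea/markov.py` | states, strategy graphs, transition matrices, cohort engine |
| `src/ptmc_cea/cea.py` | ICER/CER/NMB, dominance, report rounding |
| `src/ptmc_cea/sensitivity.py` | tornado DSA, Monte Carlo PSA, CEAC |
| `src/ptmc_cea/costs.py` | synthetic cost schedule, generation, calibration |
| `src/ptmc_cea/report.py`, `cli.py` | scenarios, full-study driver, CLI |
| `src/ptmc_cea/data/` | parameter/strategy/cost/config YAML (synthetic costs labelled as such) |
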