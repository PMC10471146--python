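# Full-study configuration: base case plus age-20/40/60 scenarios,
# one-way deterministic sensitivity analysis, and the 1,000-iteration
# probabilistic sensitivity analysis.  The cohort is followed to age 80
# (start_age + cycles = 80); the reference strategy is early surgery (ES),
# the comparator is active surveillance (AS).
parameters: table1_verbatim
strategies:
  reference: ES
  comparator: AS
costs: null               # null -> packaged synthetic schedule
calibration:
  # published base-case (age 40) lifetime totals, ¥ — calibration targets only
  targets: {ES: 53461, AS: 74198}
  rel_tol: 0.01
scenarios:
  - {start_age: 20}
  - {start_age: 40}
  - {start_age: 60}
base_start_age: 40
discount: 0.03
half_cycle: false
dsa:
  fraction: 0.10
psa:
  iterations: 1000
  seed: 20230816
wtp:
  gdp_per_capita: 80976
  multiplier: 3
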