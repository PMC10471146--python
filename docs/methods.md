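# Methods

## The decision problem

Papillary thyroid microcarcinoma (PTMC, papillary thyroid cancer < 1 cm) is
heavily overdiagnosed, and most incidentally detected tumors never progress.
Two management strategies compete: **early surgery** (ES) — upfront
hemithyroidectomy followed by routine monitoring — and **active
surveillance** (AS) — scheduled imaging and labs of the untreated tumor,
operating only on progression. The package evaluates their lifetime costs
(¥, Chinese healthcare payer perspective) and quality-adjusted life years
(QALYs) for a reference cohort of 40-year-old women followed to age 80, and
asks whether the extra cost of one strategy is justified at a
willingness-to-pay (WTP) threshold of three times China's 2021 per-capita
GDP (3 × ¥80,976 = ¥242,928/QALY).

## Cohort model

The model is an annual-cycle Markov cohort simulation. Each strategy is a
directed state graph; a probability-distributed cohort is advanced by
row-stochastic transition matrices, one cycle per year of age, for
`80 − start_age` cycles (60/40/20 cycles for start ages 20/40/60).

**Active surveillance** starts in a stable-surveillance state. Primary
tumor growth moves the cohort into a one-cycle hemithyroidectomy (HT)
tunnel; nodal metastasis into a total-thyroidectomy (TT) tunnel. Each
surgery tunnel splits the next cycle into perioperative death, permanent
and temporary complication states, and a no-complication state (temporary
complications resolve to no-complication after one cycle; permanent states
persist until death). Recurrence after HT triggers TT; recurrence after TT
triggers redo/lateral lymph node dissection (LND), with its own
complication split.

**Early surgery** places the whole cohort in the HT tunnel at cycle 0 (so
the surgery cost is charged undiscounted) and reuses the same downstream
machinery.

Age-dependence enters through two decade-banded schedules (probabilities of
tumor growth and of nodal metastasis, ages 20–79 in inclusive integer
bands); the probability for cycle *k* is looked up at age
`start_age + k`, i.e. the age entering the cycle. Cohorts simulated past
age 79 reuse the 70–79 band. All other transition probabilities are
age-constant. Background (all-cause) mortality is off by default — the
input table carries only perioperative mortality — but `run_cohort` accepts
an external life-table schedule.

Multi-year incidences are harmonized to the 1-year cycle with the
constant-rate conversion `r = −ln(1−p)/t` and its inverse
`p = 1 − e^{−rt}`; the two round-trip to machine precision.

### Reward accrual and discounting

State-membership rewards (utilities and per-cycle costs) accrue at the end
of each cycle: the total over `N` cycles is `Σ_{k=1..N} (1+d)^{−k} · occ_k·r`
with discount rate `d = 0.03` per year by default (one-way range 1–5%). A
deathless unit-utility cohort therefore accrues exactly the 40-cycle
annuity factor `(1 − 1.03^{−40})/0.03 = 23.1148` QALYs. One-time entry
costs (surgeries, complication management) are charged to the flow entering
the state in that cycle at that cycle's discount factor; initial occupancy
is charged undiscounted. A half-cycle correction (half weight on the first
and last rows) is available behind `half_cycle=True` but off by default —
the annual cycle is short relative to the horizon and the published
analysis gives no indication of using one.

Numerical guards: each matrix row must sum to 1 within 1e−12 (a state whose
named edges exceed 1 aborts naming the state and the offending sum — the
residual edge receives `1 − Σ`), and every occupancy row must conserve mass
within 1e−10 or the run aborts with the cycle index.

### Parameter interpretation choices

The published input table and text disagree on the decade-band progression
values by roughly a factor of ten (the text derives 0.38%/year from a
10-year cumulative 3.7%, while the table prints 0.0380 for the same ages,
and 0.22 for ages 20–29 — a plausible 10-year cumulative value). Rather
than assert either reading, the package ships both as selectable parameter
files: `table1_verbatim` (table values taken as annual probabilities — the
default, since those are the model's declared inputs) and `text_canonical`
(decade values treated as 10-year cumulative incidences and converted at
load time). The conversion is logged; no result asserts which reading the
original analysis used.

Utilities are loaded verbatim, including two strategy-level rows flagged at
load time as implausible for state weights ("active surveillance" 0.11,
"disease progression" 0.54 — neither is bound to a state). One utility row
prints a point value (0.6729) inconsistent with its distribution mean
(0.6279); both are kept and the mismatch flagged.

One binding is a deliberate design choice: monitored post-HT years in the
**ES arm** carry the strategy-level "early surgery" utility (0.74) rather
than the 0.99 no-complication utility used for the AS arm's post-HT state.
The published comparison makes surveillance decisively more effective than
surgery over identical horizons; with both arms' monitored years at 0.99,
the effect difference would reduce to the small complication burden and the
ordering would be an artifact of sampling noise. The strategy-level utility
rows in the input table exist precisely for such weighting, and this is the
smallest structural assumption that reproduces the published qualitative
result (surveillance more effective, every probabilistic draw in the
costlier-and-more-effective quadrant). It is recorded in the ES strategy
file and here; users can rebind it in a custom strategy file.

The surgery-outcome row "stable disease after HT" (0.684) cannot be a
coherent standalone split probability (the printed complication and death
probabilities leave 0.284 unexplained); it is bound as an explicit
HT-tunnel → no-complication edge whose residual shares the destination, so
the row is auditable in the mapping table but varying it alone does not
move results.

## Cost model (synthetic)

The study's itemized hospital costs are not published. The package ships a
clearly labelled SYNTHETIC schedule of plausible Chinese tertiary-hospital
charges (¥, 2021): five one-time event costs (HT ¥20,000; TT ¥28,000; redo
LND ¥32,000; permanent/temporary complication management ¥6,000/¥2,500)
and recurring items composing three per-cycle costs — an AS surveillance
year (two semi-annual visits with neck ultrasound, thyroid function/blood
tests and laryngoscopy, plus one chest CT and one enhanced neck CT a year,
¥3,010 at defaults), a lighter post-surgery follow-up year (two visits
with ultrasound and labs, ¥1,260), and follow-up plus a year of thyroxine
supplementation (¥2,060) for states with lost thyroid function. Each item
carries a documented plausibility range (used by `generate_cost_schedule`,
which draws a schedule uniformly from the ranges, deterministically under a
seed) and a 10% normal SD for probabilistic draws.

The asymmetry between the surveillance year and the follow-up year is a
modelling decision: the published lifetime ES cost is essentially identical
(~¥53,450) across 20-, 40- and 60-year horizons, which is only possible if
the ES arm accrues little recurring cost; a shared recurring schedule also
makes the calibration below infeasible. The synthetic schedule therefore
gives post-surgery follow-up a lighter regimen than active surveillance.

**Calibration.** Items belong to two groups — surgical (events) and
surveillance (recurring) — each with a scale factor. Discounted lifetime
cost is exactly linear and homogeneous in the two factors, so matching the
two published base-case totals (ES ¥53,461, AS ¥74,198 at age 40) is a
2×2 linear solve assembled from model evaluations at factor pairs (1,0) and
(0,1); the solution is clamped to bounds, verified by a rerun, and flagged
non-converged with residuals if the verification misses either target by
more than 1% relatively. At the packaged defaults the factors come out near
one (≈0.79 surgical, ≈1.17 surveillance) and the targets are hit to
machine precision. Calibration is idempotent by construction.

The published totals are *calibration targets, not reproductions*: they
rest on unavailable cost data, an under-specified state structure, and
internally inconsistent printed values (a constant 5.2 ES QALYs across
20-to-60-year horizons; acceptability-curve landmarks incompatible with the
base-case ICER). The package reports its own totals and flags, and no test
asserts the published QALY totals or ICER.

## Cost-effectiveness metrics

For reference strategy ES and comparator AS with totals `(C_i, E_i)`:
ΔC = C_AS − C_ES, ΔE = E_AS − E_ES, ICER = ΔC/ΔE, CER_i = C_i/E_i, and net
monetary benefit `NMB_i(λ) = λ·E_i − C_i` at WTP λ. ICER is undefined
(NaN, labelled) at ΔE = 0; a cheaper-and-more-effective comparator is
labelled *dominant* while the signed negative ratio is still reported,
matching the published table's reporting style. For ΔE > 0, `ICER < λ` is
equivalent to `NMB_AS > NMB_ES` (property-tested). Report tables round
currency to integer ¥, QALYs to 0.1 and ratios to integer ¥/QALY; internal
arithmetic is full precision.

## Sensitivity analyses

**One-way deterministic (tornado).** Each input in turn is pinned at the
ends of its analysis range — the published range where printed, otherwise
±10% clipped to the legal domain, and 1–5% for the discount rate — with all
else at base case; both strategies are re-run and the ICER spread recorded,
sorted descending. Cost items participate alongside probabilities and
utilities; qualified names (`p:`, `u:`, `c:`) disambiguate the one
colliding row name. Only one input moves at a time (no two-way grids).

**Probabilistic (PSA).** 1,000 Monte Carlo iterations by default. Per
iteration all uncertain inputs are drawn jointly and *independently* —
probabilities and utilities from beta distributions parameterized by the
method of moments from their printed mean/SD, cost items from normals
truncated at zero by resampling — and both strategies run on the same draw.
Independence is the standard default in the absence of a published
correlation structure, and a documented limitation. Outputs: the
incremental cost-effect cloud (CE plane), quadrant fractions, and the
cost-effectiveness acceptability curve (CEAC): at each WTP on a default
grid of 0 to ¥242,928 in 101 steps, the fraction of iterations where the
comparator has the higher NMB. All draws flow from one `numpy` generator
seeded by the caller; identical seeds give identical results bit-for-bit.

## What the synthetic setup does and does not show

The synthetic generator emulates the *structure* of the study conditions —
itemized semi-annual surveillance vs lighter post-operative follow-up,
one-time surgery and complication charges, 10% cost uncertainty, beta
uncertainty on probabilities and utilities — calibrated so the base-case
cost totals match the published ones. It does not reproduce the actual
hospital price list, any real cost correlation structure, patient-level
heterogeneity, or non-medical/indirect costs (excluded by design). Passing
tests therefore demonstrate the correctness and internal consistency of
the model machinery and the qualitative robustness of the
surveillance-favouring conclusion under these conditions — not a
reproduction of the published cost or QALY totals, which the packaged
base case does not match (our model yields ≈4 incremental QALYs at age 40,
not 20.6, and an ICER of ≈¥5,100/QALY, not ¥1,009 — same decision, both
far below the threshold).

## Default problem sizes

Base case: start age 40, 40 annual cycles (subgroups 20/60 run 60/20
cycles); PSA 1,000 iterations; beta moment-recovery checks use 10⁶ draws;
the test suite's property checks use dozens of random parameter draws per
invariant. A full study (calibration + three scenarios + 40-entry tornado +
1,000-iteration PSA) completes in a few seconds on one CPU.

## Known limitations

- The state graph is the smallest one consistent with the published
  treatment mapping; pathways the inputs do not parameterize (e.g. direct
  lateral metastasis without prior TT, recurrence out of permanent
  complication states) are absent.
- No background mortality by default; lifetime horizons end by truncation
  at age 80, not by death.
- Utilities and probabilities are age-constant apart from the two
  progression schedules.
- Parameter draws are independent; costs and probabilities share no
  correlation.
- The ES-arm monitored-state utility binding (0.74) is an interpretive
  choice, documented above; rebinding it to 0.99 shrinks the incremental
  effect to the complication burden alone.
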