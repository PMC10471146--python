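# Alternative reading of the published inputs: decade-band progression values
# are treated as 10-year cumulative incidences and converted to annual
# probabilities at load time via r = -ln(1-p)/t, t = 10 (the conversion the
# source text documents: 10-year 3.7% -> 0.38%/year).  All other rows are
# identical to parameters_table1_verbatim.yaml.
name: text_canonical
discount_rate: 0.03

probabilities:
  permanent_complication_from_ht:
    {point: 0.015, distribution: beta, mean: 0.016, sd: 0.0008, dsa_range: [0.014, 0.017]}
  temporary_complication_from_ht:
    {point: 0.015, distribution: beta, mean: 0.016, sd: 0.0008, dsa_range: [0.014, 0.017]}
  recurrence_after_ht:
    {point: 0.004, distribution: beta, mean: 0.004, sd: 0.0002, dsa_range: [0.0036, 0.0044]}
  recurrence_after_tt:
    {point: 0.008, distribution: beta, mean: 0.008, sd: 0.0005, dsa_range: [0.007, 0.009]}
  stable_disease_after_ht:
    {point: 0.684, distribution: beta, mean: 0.684, sd: 0.035, dsa_range: [0.616, 0.752]}
  permanent_unilateral_rln_injury_after_tt:
    {point: 0.015, distribution: beta, mean: 0.016, sd: 0.0008, dsa_range: [0.014, 0.017]}
  hypoparathyroidism_after_tt:
    {point: 0.089, distribution: beta, mean: 0.09, sd: 0.005, dsa_range: [0.080, 0.098]}
  permanent_bilateral_rln_injury_after_tt:
    {point: 0.003, distribution: beta, mean: 0.003, sd: 0.0002, dsa_range: [0.0027, 0.0033]}
  death_after_ht:
    {point: 0.002, distribution: beta, mean: 0.002, sd: 0.0001, dsa_range: [0.0018, 0.0022]}
  death_after_tt:
    {point: 0.002, distribution: beta, mean: 0.002, sd: 0.0001, dsa_range: [0.0018, 0.0022]}
  complication_from_redo_lnd:
    {point: 0.32, distribution: beta, mean: 0.32, sd: 0.16, dsa_range: [0.288, 0.352]}

utilities:
  as_stable_disease:
    {point: 0.99, distribution: beta, mean: 0.99, sd: 0.05, dsa_range: [0.89, 1.0]}
  no_complication_after_ht:
    {point: 0.99, distribution: beta, mean: 0.99, sd: 0.05, dsa_range: [0.89, 1.0]}
  permanent_complication_after_ht:
    {point: 0.63, distribution: beta, mean: 0.63, sd: 0.032, dsa_range: [0.57, 0.69]}
  temporary_complication_after_ht:
    {point: 0.627, distribution: beta, mean: 0.627, sd: 0.032, dsa_range: [0.56, 0.69]}
  permanent_bilateral_rln_injury_after_tt:
    {point: 0.21, distribution: beta, mean: 0.21, sd: 0.01, dsa_range: [0.19, 0.23]}
  permanent_hypoparathyroidism_after_tt:
    {point: 0.778, distribution: beta, mean: 0.778, sd: 0.039, dsa_range: [0.70, 0.86]}
  # Source table prints point 0.6729 but mean 0.6279 (apparent transposition);
  # both are kept verbatim and the loader flags the mismatch.
  permanent_unilateral_rln_injury_after_tt:
    {point: 0.6729, distribution: beta, mean: 0.6279, sd: 0.032, dsa_range: [0.57, 0.69]}
  redo_lnd:
    {point: 0.56, distribution: beta, mean: 0.56, sd: 0.029, dsa_range: [0.50, 0.62]}
  lnd_complication:
    {point: 0.41, distribution: beta, mean: 0.41, sd: 0.02, dsa_range: [0.37, 0.45]}
  no_complication_after_tt:
    {point: 0.83, distribution: beta, mean: 0.83, sd: 0.042, dsa_range: [0.75, 0.91]}
  # Strategy-level utility; implausibly low for asymptomatic surveillance and
  # left unbound by the packaged strategy graphs (flagged at load time).
  active_surveillance:
    {point: 0.11, distribution: beta, mean: 0.11, sd: 0.006, dsa_range: [0.10, 0.12]}
  disease_progression:
    {point: 0.54, distribution: beta, mean: 0.54, sd: 0.028, dsa_range: [0.49, 0.59]}
  early_surgery:
    {point: 0.74, distribution: beta, mean: 0.74, sd: 0.038, dsa_range: [0.67, 0.81]}
  nodal_metastasis:
    {point: 0.25, distribution: beta, mean: 0.25, sd: 0.013, dsa_range: [0.23, 0.28]}
  primary_tumor_growth:
    {point: 0.54, distribution: beta, mean: 0.54, sd: 0.028, dsa_range: [0.49, 0.59]}
  recurrence:
    {point: 0.54, distribution: beta, mean: 0.54, sd: 0.028, dsa_range: [0.49, 0.59]}

age_schedules:
  nodule_growth:
    interpretation: cumulative_10yr
    bands:
      - {ages: [20, 29], value: 0.22}
      - {ages: [30, 39], value: 0.084}
      - {ages: [40, 49], value: 0.0380}
      - {ages: [50, 59], value: 0.0240}
      - {ages: [60, 69], value: 0.0003}
      - {ages: [70, 79], value: 0.0006}
  nodal_metastasis:
    interpretation: cumulative_10yr
    bands:
      - {ages: [20, 29], value: 0.165}
      - {ages: [30, 39], value: 0.061}
      - {ages: [40, 49], value: 0.0380}
      - {ages: [50, 59], value: 0.0240}
      - {ages: [60, 69], value: 0.0068}
      - {ages: [70, 79], value: 0.0036}
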