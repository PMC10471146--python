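# Early-surgery strategy graph.
#
# The cohort undergoes hemithyroidectomy (HT) at cycle 0 (the whole cohort
# starts in the one-cycle ht_surgery tunnel, so the surgery cost is charged
# undiscounted and the outcome split happens at the first transition).
# Recurrence in the remaining lobe after HT triggers total thyroidectomy (TT);
# recurrence after TT triggers redo lymph node dissection (LND).
#
# Monitored post-HT years are weighted by the strategy-level "early surgery"
# utility (0.74) rather than the 0.99 no-complication utility: the published
# strategy comparison makes surveillance decisively more effective over equal
# horizons, which is only structurally possible if monitored post-surgery
# years under early surgery carry the strategy-level weight the input table
# provides for them.  See docs/methods.md.
#
# Probability-row -> edge mapping (audit table):
#   death_after_ht                            ht_surgery -> death
#   permanent_complication_from_ht            ht_surgery -> post_ht_perm
#   temporary_complication_from_ht            ht_surgery -> post_ht_temp
#   stable_disease_after_ht                   ht_surgery -> post_ht_no_comp
#     (explicit edge sharing its destination with the residual edge)
#   recurrence_after_ht                       post_ht_no_comp -> tt_surgery
#   death_after_tt                            tt_surgery -> death
#   hypoparathyroidism_after_tt               tt_surgery -> post_tt_hypopara
#   permanent_unilateral_rln_injury_after_tt  tt_surgery -> post_tt_uni_rln
#   permanent_bilateral_rln_injury_after_tt   tt_surgery -> post_tt_bi_rln
#   recurrence_after_tt                       post_tt_no_comp -> lnd_surgery
#   complication_from_redo_lnd                lnd_surgery -> post_lnd_comp
name: ES

states:
  - name: ht_surgery
    utility: early_surgery
    cycle_cost: followup_year
    entry_cost: ht_surgery
    tunnel: true
  - name: post_ht_no_comp
    utility: early_surgery
    cycle_cost: followup_year
  - name: post_ht_perm
    utility: permanent_complication_after_ht
    cycle_cost: followup_thyroxine_year
    entry_cost: permanent_complication_mgmt
    permanent: true
  - name: post_ht_temp
    utility: temporary_complication_after_ht
    cycle_cost: followup_year
    entry_cost: temporary_complication_mgmt
    tunnel: true
  - name: tt_surgery
    utility: recurrence
    cycle_cost: followup_year
    entry_cost: tt_surgery
    tunnel: true
  - name: post_tt_no_comp
    utility: no_complication_after_tt
    cycle_cost: followup_thyroxine_year
  - name: post_tt_hypopara
    utility: permanent_hypoparathyroidism_after_tt
    cycle_cost: followup_thyroxine_year
    entry_cost: permanent_complication_mgmt
    permanent: true
  - name: post_tt_uni_rln
    utility: permanent_unilateral_rln_injury_after_tt
    cycle_cost: followup_thyroxine_year
    entry_cost: permanent_complication_mgmt
    permanent: true
  - name: post_tt_bi_rln
    utility: permanent_bilateral_rln_injury_after_tt
    cycle_cost: followup_thyroxine_year
    entry_cost: permanent_complication_mgmt
    permanent: true
  - name: lnd_surgery
    utility: recurrence
    cycle_cost: followup_thyroxine_year
    entry_cost: redo_lnd
    tunnel: true
  - name: post_lnd_no_comp
    utility: redo_lnd
    cycle_cost: followup_thyroxine_year
  - name: post_lnd_comp
    utility: lnd_complication
    cycle_cost: followup_thyroxine_year
    entry_cost: permanent_complication_mgmt
    permanent: true
  - name: death
    absorbing: true

initial_occupancy:
  ht_surgery: 1.0

transitions:
  - {from: ht_surgery, to: death, param: death_after_ht}
  - {from: ht_surgery, to: post_ht_perm, param: permanent_complication_from_ht}
  - {from: ht_surgery, to: post_ht_temp, param: temporary_complication_from_ht}
  - {from: ht_surgery, to: post_ht_no_comp, param: stable_disease_after_ht}
  - {from: ht_surgery, to: post_ht_no_comp, residual: true}

  - {from: post_ht_no_comp, to: tt_surgery, param: recurrence_after_ht}
  - {from: post_ht_no_comp, to: post_ht_no_comp, residual: true}
  - {from: post_ht_perm, to: post_ht_perm, residual: true}
  - {from: post_ht_temp, to: post_ht_no_comp, residual: true}

  - {from: tt_surgery, to: death, param: death_after_tt}
  - {from: tt_surgery, to: post_tt_hypopara, param: hypoparathyroidism_after_tt}
  - {from: tt_surgery, to: post_tt_uni_rln, param: permanent_unilateral_rln_injury_after_tt}
  - {from: tt_surgery, to: post_tt_bi_rln, param: permanent_bilateral_rln_injury_after_tt}
  - {from: tt_surgery, to: post_tt_no_comp, residual: true}

  - {from: post_tt_no_comp, to: lnd_surgery, param: recurrence_after_tt}
  - {from: post_tt_no_comp, to: post_tt_no_comp, residual: true}
  - {from: post_tt_hypopara, to: post_tt_hypopara, residual: true}
  - {from: post_tt_uni_rln, to: post_tt_uni_rln, residual: true}
  - {from: post_tt_bi_rln, to: post_tt_bi_rln, residual: true}

  - {from: lnd_surgery, to: post_lnd_comp, param: complication_from_redo_lnd}
  - {from: lnd_surgery, to: post_lnd_no_comp, residual: true}
  - {from: post_lnd_no_comp, to: post_lnd_no_comp, residual: true}
  - {from: post_lnd_comp, to: post_lnd_comp, residual: true}
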