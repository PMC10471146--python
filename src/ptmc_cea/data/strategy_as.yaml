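# Active-surveillance strategy graph.
#
# The cohort starts under surveillance with the untreated microcarcinoma.
# Primary tumor growth triggers hemithyroidectomy (HT, with isthmectomy and
# unilateral central neck dissection); nodal metastasis triggers total
# thyroidectomy (TT, with central neck dissection); recurrence after TT
# triggers lateral / redo lymph node dissection (LND).  Surgery states are
# one-cycle tunnels that split into complication outcomes the following cycle.
#
# Probability-row -> edge mapping (audit table):
#   nodule_growth (schedule)                  stable_as -> ht_surgery
#   nodal_metastasis (schedule)               stable_as -> tt_surgery
#   death_after_ht                            ht_surgery -> death
#   permanent_complication_from_ht            ht_surgery -> post_ht_perm
#   temporary_complication_from_ht            ht_surgery -> post_ht_temp
#   stable_disease_after_ht                   ht_surgery -> post_ht_no_comp
#     (explicit edge; the residual edge of ht_surgery has the same
#      destination, so the outcome split stays mass-consistent and varying
#      this row alone does not move results)
#   recurrence_after_ht                       post_ht_no_comp -> tt_surgery
#   death_after_tt                            tt_surgery -> death
#   hypoparathyroidism_after_tt               tt_surgery -> post_tt_hypopara
#   permanent_unilateral_rln_injury_after_tt  tt_surgery -> post_tt_uni_rln
#   permanent_bilateral_rln_injury_after_tt   tt_surgery -> post_tt_bi_rln
#   recurrence_after_tt                       post_tt_no_comp -> lnd_surgery
#   complication_from_redo_lnd                lnd_surgery -> post_lnd_comp
name: AS

states:
  - name: stable_as
    utility: as_stable_disease
    cycle_cost: surveillance_year
  - name: ht_surgery
    utility: primary_tumor_growth
    cycle_cost: followup_year
    entry_cost: ht_surgery
    tunnel: true
  - name: post_ht_no_comp
    utility: no_complication_after_ht
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
    utility: nodal_metastasis
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
  stable_as: 1.0

transitions:
  - {from: stable_as, to: ht_surgery, schedule: nodule_growth}
  - {from: stable_as, to: tt_surgery, schedule: nodal_metastasis}
  - {from: stable_as, to: stable_as, residual: true}

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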