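# SYNTHETIC cost schedule.
#
# These are NOT actual hospital prices.  They are plausible order-of-magnitude
# charges for a Chinese tertiary general hospital (¥, price year 2021),
# itemized so that individual components can be varied, and intended to be
# scaled by calibrate_costs() against published lifetime totals.  Each item
# carries a plausibility range (used by generate_cost_schedule) and belongs to
# one of two calibration groups: "surgical" (one-time event costs) or
# "surveillance" (recurring per-cycle costs).
#
# Composite per-cycle costs:
#   surveillance_year        two semi-annual surveillance visits (office visit,
#                            neck ultrasound, thyroid function/blood tests,
#                            laryngoscopy) plus one chest CT and one enhanced
#                            neck CT per year
#   followup_year            lighter post-surgery follow-up (two visits with
#                            ultrasound and labs, no laryngoscopy/CT)
#   followup_thyroxine_year  follow-up plus a year of thyroxine
#                            supplementation and its monitoring
name: synthetic_default
currency: CNY
price_year: 2021
sd_fraction: 0.10   # per-item normal SD for probabilistic draws, as share of value

items:
  # one-time event costs (group: surgical)
  ht_surgery:                  {value: 20000, range: [15000, 28000], group: surgical}
  tt_surgery:                  {value: 28000, range: [20000, 38000], group: surgical}
  redo_lnd:                    {value: 32000, range: [24000, 45000], group: surgical}
  permanent_complication_mgmt: {value: 6000,  range: [3000, 10000],  group: surgical}
  temporary_complication_mgmt: {value: 2500,  range: [1000, 5000],   group: surgical}
  # recurring per-visit / per-year costs (group: surveillance)
  office_visit:                {value: 30,   range: [7, 100],     group: surveillance}
  neck_ultrasound:             {value: 250,  range: [150, 400],   group: surveillance}
  thyroid_function_labs:       {value: 350,  range: [200, 500],   group: surveillance}
  laryngoscopy:                {value: 200,  range: [100, 300],   group: surveillance}
  chest_ct:                    {value: 550,  range: [350, 800],   group: surveillance}
  neck_ct_enhanced:            {value: 800,  range: [500, 1100],  group: surveillance}
  thyroxine_year:              {value: 800,  range: [500, 1200],  group: surveillance}

compositions:
  surveillance_year:
    - {item: office_visit, times: 2}
    - {item: neck_ultrasound, times: 2}
    - {item: thyroid_function_labs, times: 2}
    - {item: laryngoscopy, times: 2}
    - {item: chest_ct, times: 1}
    - {item: neck_ct_enhanced, times: 1}
  followup_year:
    - {item: office_visit, times: 2}
    - {item: neck_ultrasound, times: 2}
    - {item: thyroid_function_labs, times: 2}
  followup_thyroxine_year:
    - {item: office_visit, times: 2}
    - {item: neck_ultrasound, times: 2}
    - {item: thyroid_function_labs, times: 2}
    - {item: thyroxine_year, times: 1}
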