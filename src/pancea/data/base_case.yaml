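# Base-case inputs for the pancreatic-cancer M-staging cost-effectiveness
# model.  One row per model input; currency is unit-less USD of the source
# cost year.  Structural flags at the bottom are the configuration selected
# by the structure search (see pancea.sensitivity.structure_search).

# --- decision framing ------------------------------------------------------
start_age: 70            # expected age at the diagnostic procedure, years
horizon: 5               # Markov time horizon, annual cycles
discount_rate: 0.03      # per-year discount on costs and QALYs
wtp: 100000.0            # willingness-to-pay per QALY, USD

# --- diagnostic test performance ------------------------------------------
p_ct_tp: 0.9225          # CE-CT correctly classifies the tumor as resectable
p_ct_fp: 0.0775          # CE-CT false-positive resectability (occult M1)
p_mri_detect: 1.0        # added liver MRI detects occult M1 among CT false positives

# --- one-time costs (acute) -----------------------------------------------
cost_ct: 692.0           # CT chest/abdomen/pelvis (Medicare schedule)
cost_mri: 615.0          # MRI abdomen (Medicare schedule)
cost_surgery: 42869.0    # pancreatic resection incl. complications

# --- annual costs (long term) ---------------------------------------------
cost_m1_therapy: 60000.0         # palliative therapy, metastatic, not resected
cost_post_surgery_y1: 36126.0    # therapy/follow-up after surgery, first year
cost_post_surgery_later: 1126.0  # therapy/follow-up after surgery, later years
cost_m1_after_surgery: 60000.0   # therapy after resection with metastases
cost_local_recurrence: 30000.0   # therapy with local recurrence / R1 situation

# --- utilities (QALY weights) ---------------------------------------------
u_m1_post_surgery: 0.6       # metastatic after surgery
u_m1_no_surgery: 0.65        # metastatic without surgery
u_m0_post_surgery_y1: 0.726  # resected, metastasis-free, first year ("text" set)
u_m0_post_surgery_later: 0.797  # resected, metastasis-free, later years ("text" set)
u_dead: 0.0

# --- transition probabilities ---------------------------------------------
p_r1: 0.8                   # proportion of resections with R1/local recurrence
p_met_after_resection: 0.38 # per-year metastasis after resection
p_surgery_death: 0.037      # perioperative mortality, applied once at resection
p_death_m1: 0.5074          # per-year mortality with metastatic disease
p_death_m0: 0.029           # per-year mortality without metastatic disease

# --- structural configuration (structure-search selected) ------------------
structure:
  half_cycle_correction: false
  accrual: begin
  terminal_stage: true
  utility_set: text
  r1_split_timing: at_entry
  r1_mortality: m0
  r1_cost_schedule: first_year_replaced
  met_cost_schedule: plus_followup
  surgery_cost_scope: staged_resectable
  first_year_reference: global
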