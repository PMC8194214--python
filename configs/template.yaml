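# Annotated parameter template for the appendicitis cost-effectiveness model.
#
# Any key omitted here falls back to the documented synthetic baseline
# (see appendix_cea.parameters.PROVENANCE).  Fields marked
#   provenance: "transcribe-from-Supplementary"
# are placeholders: replace them with the exact values of the source tariff /
# probability / utility tables before using the model for a real decision.
# Currency inputs are COP tariffs; the engine converts to USD after the
# guideline +30% inflation adjustment.

provenance:
  note: >
    Placeholder values below reproduce the package baseline.  Every field
    tagged transcribe-from-Supplementary should be replaced by the exact
    source value; untagged fields are public anchors (trial results,
    guideline constants).

# --- probabilities -----------------------------------------------------------
p_oa_ssi: 0.10            # provenance: "transcribe-from-Supplementary"
p_oa_abscess: 0.012       # provenance: "transcribe-from-Supplementary"
p_oa_ileus: 0.05          # provenance: "transcribe-from-Supplementary"
rr_la_ssi: 0.35           # provenance: "transcribe-from-Supplementary" (meta-analytic RR)
rr_la_abscess: 1.77       # provenance: "transcribe-from-Supplementary"
rr_la_ileus: 0.40         # provenance: "transcribe-from-Supplementary"
p_nom_success: 0.727      # APPAC trial: antibiotic success within 5 years
p_nom_initial_failure: 0.0    # failure within the initial 72 h admission (0 folds it into year 1)
p_recur_complicated: 0.10     # provenance: "transcribe-from-Supplementary"
p_choose_oa: 0.929            # share of appendectomies performed open
p_complicated_medical: 0.60   # provenance: "transcribe-from-Supplementary"

# Conditional per-year recurrence hazards after initial NOM success.
# Omit to derive the default shape (27% cumulative failure at year 1, linear
# to 1 - p_nom_success at the horizon).  If given, the implied success must
# equal p_nom_success.
# recurrence_schedule: {1: 0.27, 2: ..., 3: ..., 4: ..., 5: ...}

# --- utilities (weight in [0,1], episode duration in years) ------------------
utilities:
  healthy: {utility: 0.998, duration_years: 5.0}            # background state
  post_surgery_la: {utility: 0.88, duration_years: 0.0833}  # provenance: "transcribe-from-Supplementary"
  post_surgery_oa: {utility: 0.85, duration_years: 0.1667}  # provenance: "transcribe-from-Supplementary"
  ssi: {utility: 0.82, duration_years: 0.0577}              # provenance: "transcribe-from-Supplementary"
  abscess: {utility: 0.74, duration_years: 0.10}            # provenance: "transcribe-from-Supplementary"
  nom_initial: {utility: 0.90, duration_years: 0.02}        # provenance: "transcribe-from-Supplementary"
  complicated_aa: {utility: 0.70, duration_years: 0.15}     # provenance: "transcribe-from-Supplementary"

# --- per-event costing (COP tariffs) ----------------------------------------
# provenance: "transcribe-from-Supplementary" for every quantity and tariff
cost_items:
  nom_initial:
    - {resource: hospital_day, quantity: 3, unit_cost_cop: 80000}
    - {resource: surgeon_evaluation, quantity: 2, unit_cost_cop: 35000}
    - {resource: iv_fluids, quantity: 6, unit_cost_cop: 15000}
    - {resource: analgesic_dose, quantity: 9, unit_cost_cop: 3000}
    - {resource: c_reactive_protein, quantity: 2, unit_cost_cop: 25000}
    - {resource: hemogram, quantity: 2, unit_cost_cop: 20000}
    - {resource: ertapenem_1g, quantity: 3, unit_cost_cop: 90000}
    - {resource: levofloxacin_500mg, quantity: 7, unit_cost_cop: 6000}
    - {resource: metronidazole_500mg, quantity: 21, unit_cost_cop: 2000}
  ssi:
    - {resource: cephalexin_500mg, quantity: 28, unit_cost_cop: 2000}
    - {resource: medical_evaluation, quantity: 2, unit_cost_cop: 35000}
    - {resource: wound_care_session, quantity: 8, unit_cost_cop: 20000}
    - {resource: analgesic_dose, quantity: 10, unit_cost_cop: 3000}
  abscess:
    - {resource: hospital_day, quantity: 4, unit_cost_cop: 80000}
    - {resource: percutaneous_drainage, quantity: 1, unit_cost_cop: 250000}
    - {resource: ceftriaxone_1g, quantity: 8, unit_cost_cop: 12000}
    - {resource: metronidazole_500mg, quantity: 24, unit_cost_cop: 2000}
    - {resource: c_reactive_protein, quantity: 2, unit_cost_cop: 25000}
    - {resource: hemogram, quantity: 2, unit_cost_cop: 20000}
    - {resource: surgeon_evaluation, quantity: 2, unit_cost_cop: 35000}
  ileus:
    - {resource: hospital_day, quantity: 4, unit_cost_cop: 80000}
    - {resource: iv_fluids, quantity: 8, unit_cost_cop: 15000}
    - {resource: analgesic_dose, quantity: 9, unit_cost_cop: 3000}
    - {resource: nasogastric_tube, quantity: 1, unit_cost_cop: 40000}
    - {resource: hemogram, quantity: 2, unit_cost_cop: 20000}
  complicated_aa:
    - {resource: hospital_day, quantity: 5, unit_cost_cop: 80000}
    - {resource: percutaneous_drainage, quantity: 1, unit_cost_cop: 250000}
    - {resource: ceftriaxone_1g, quantity: 10, unit_cost_cop: 12000}
    - {resource: metronidazole_500mg, quantity: 30, unit_cost_cop: 2000}
    - {resource: c_reactive_protein, quantity: 3, unit_cost_cop: 25000}
    - {resource: hemogram, quantity: 3, unit_cost_cop: 20000}
    - {resource: surgeon_evaluation, quantity: 3, unit_cost_cop: 35000}

# Tariff packages (COP): the LA package is the OA package plus one disposable trocar.
package_cost_oa: 780000   # provenance: "transcribe-from-Supplementary"
package_cost_la: 795000   # provenance: "transcribe-from-Supplementary"

# --- analysis settings -------------------------------------------------------
discount_rate: 0.05       # national guideline: 5% for costs and outcomes
horizon_years: 5
wtp: 6667                 # 1 GDP per capita, USD/QALY
exchange_rate: 3478       # COP per USD, January 2021
inflation_factor: 1.30    # guideline inflation adjustment on tariffs
qaly_convention: end      # end | mid | start (annuity timing of utility streams)
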