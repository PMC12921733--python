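# Base-case parameter set for the baha_attract arm.
# AUD 2024 tariffs; probabilities per 6-month cycle; times in years.
name: baha_attract
transitions:
  explantation: 0.0125
  explantation_se: 0.0033
  revision: 0.008
  revision_se: 0.0037
  ae_reimplantation: 0.004
  ae_reimplantation_se: 0.0015
  soft_tissue: 0.0833
  soft_tissue_se: 0.017
  pain: 0.0833
  pain_se: 0.017
costs:
  device_acquisition: 8571.0
  sp_replacement_device: 6484.0
  anaesthesia_fraction: 0.5
  battery_per_cycle: 5.1
  surgery_implantation: 680.3
  anaesthesia: 225.5
  hospitalisation: 5588.26
  post_surgery_audiologist_bundle: 350.8
  post_surgery_specialist: 49.75
  sp_replacement_visit: 175.4
  ae_management_per_event: 148.7
  hcru_per_cycle: 87.7
utilities:
  on_bchi: 0.76
  on_bchi_se: 0.038
  off_bchi: 0.67
  off_bchi_se: 0.028
  on_state_decrement: -0.03
  soft_tissue_decrement: -0.03
  soft_tissue_decrement_se: 0.006
  soft_tissue_duration_years: 0.25
  pain_decrement: -0.002
  pain_decrement_se: 0.001
  subgroups:
    chl_mhl:
      on_bchi: 0.73
      on_bchi_se: 0.04
      off_bchi: 0.62
      off_bchi_se: 0.031
      on_state_decrement: -0.06
    ssd:
      on_bchi: 0.86
      on_bchi_se: 0.097
      off_bchi: 0.84
      off_bchi_se: 0.07
      on_state_decrement: -0.01
timing:
  anticipated_reimplantation_mean: 10.0
  sp_replacement_mean: 5.0
  coefficient_of_variation: 0.35
  anticipated_cv: null
  sp_cv: null
  distribution_family: gamma
  compliance_anticipated: 1.0
  compliance_sp: 1.0
  anticipated_enabled: true
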