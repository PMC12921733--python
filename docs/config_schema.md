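# Configuration file schema (normative)

One YAML file per comparator arm plus one settings file.  Currency is AUD,
probabilities are per model cycle (6 months unless `cycle_length` says
otherwise), times are years.  All fields are required unless a default is
stated.  The bundled files under `src/bchicea/data/configs/` are complete
examples.

## Comparator parameter file

```yaml
name: <identifier, unique within a comparison>

transitions:            # per-cycle probabilities, each with a standard error
  explantation: <0..1>          # permanent move to off-BCHI
  explantation_se: <>=0>
  revision: <0..1>              # within-state revision surgery
  revision_se: <>=0>
  ae_reimplantation: <0..1>     # first implant -> second implant, once
  ae_reimplantation_se: <>=0>
  soft_tissue: <0..1>           # adverse event, no state change
  soft_tissue_se: <>=0>
  pain: <0..1>                  # adverse event, no state change
  pain_se: <>=0>
  # constraint: explantation + ae_reimplantation <= 1

costs:                  # AUD
  device_acquisition: <>=0>
  sp_replacement_device: <>=0>
  surgery_implantation: <>=0>
  anaesthesia: <>=0>
  anaesthesia_fraction: <0..1>  # share of procedures under anaesthesia
  hospitalisation: <>=0>
  post_surgery_audiologist_bundle: <>=0>   # two audiologist visits
  post_surgery_specialist: <>=0>           # one surgical follow-up
  sp_replacement_visit: <>=0>              # one audiologist visit
  ae_management_per_event: <>=0>           # two specialist appointments
  hcru_per_cycle: <>=0>                    # routine maintenance, per cycle on BCHI
  battery_per_cycle: <>=0>                 # per cycle on BCHI

utilities:
  on_bchi: <0..1>
  on_bchi_se: <>=0>
  off_bchi: <0..1>
  off_bchi_se: <>=0>
  on_state_decrement: <=0, default 0>      # applied to on-state utility
  soft_tissue_decrement: <=0>              # utility decrement per episode
  soft_tissue_decrement_se: <>=0>
  soft_tissue_duration_years: <>0, default 0.25>
  pain_decrement: <=0>                     # QALY loss per event (pre-scaled)
  pain_decrement_se: <>=0>
  subgroups:                               # optional named variants
    <name>: {on_bchi, on_bchi_se, off_bchi, off_bchi_se, on_state_decrement}

timing:
  anticipated_reimplantation_mean: <>0>    # years
  sp_replacement_mean: <>0>                # years
  coefficient_of_variation: <>0, default 0.35>
  anticipated_cv: <>0 or null>             # per-event override
  sp_cv: <>0 or null>
  distribution_family: gamma | lognormal | deterministic
  compliance_anticipated: <0..1, default 1>
  compliance_sp: <0..1, default 1>
  anticipated_enabled: <bool, default true>
```

## Settings file

```yaml
cycle_length: <>0, years, default 0.5>
horizon: <years >= cycle_length, or "lifetime">
discount_rate_costs: <>=0, annual, default 0.05>
discount_rate_qalys: <>=0, annual, default 0.05>
start_age: <>=0, default 40>
sex_mix: <0..1, proportion female, default 0.5>
half_cycle_correction: <bool, default true>
wtp_threshold: <>=0, AUD/QALY, default 50000>
discount_compounding: annual | cycle      # default annual (year-step factor)
event_discount_timing: start | midpoint | end   # default start
utility_subgroup: all | <subgroup name>   # default all
```

## Life table

Tab-separated text with comment lines starting `#` and columns
`age` (contiguous integers from 0), `sex` (`female` / `male`), `q_annual`
(annual death probability in [0, 1], equal to 1 at the terminal age, which
must be at least 100).
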