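# bchicea

A Markov cohort cost-utility model for bone-conduction hearing implant
(BCHI) systems in the Australian healthcare setting.

BCHIs treat conductive or mixed hearing loss and single-sided deafness when
conventional hearing aids are unsuitable.  Reimbursement decisions need to
know whether a newer active transcutaneous system is worth funding against
the alternatives, so this package models the full economic pathway of an
implanted cohort — device acquisition, surgery, hospitalisation, revisions,
explantations, adverse-event-driven and anticipated reimplantations,
sound-processor (SP) and battery replacement, routine maintenance — and
compares two device arms on discounted costs and quality-adjusted life
years (QALYs).  It is written for health-economics analysts: a Python API
with bundled base-case inputs for four systems (Sentio, Osia, Ponto, Baha
Attract), plus a thin CLI.

## Model in brief

Four health states — on BCHI (1st implant), on BCHI (2nd implant, reached by
at most one AE-driven reimplantation), off BCHI (after explantation), dead —
advance in 6-month cycles over a 15-year horizon (base case), with age- and
sex-specific background mortality identical in both arms.  Per-patient
discounted outcomes:

- **Costs**: per-procedure bundles at event rates, recurring device-clock
  events (anticipated reimplantation, SP replacement) as gamma renewal
  processes, per-cycle maintenance/battery while on the device; annual 5%
  discounting with half-cycle correction.
- **QALYs**: Σ_j D(t_j)·Δ·[u_on·occ_on(j) + u_off·occ_off(j)] plus
  per-event adverse-event disutilities.
- **Comparison**: ΔC, ΔQ, ICER = ΔC/ΔQ (trade-off quadrants only), net
  monetary benefit NMB = λ·ΔQ − ΔC at λ = 50,000 AUD/QALY, and a dominance
  classification.

Uncertainty is covered three ways: a tornado of one-way 95%-CI reruns, a
deterministic scenario catalog (discounting, horizons, cycle length,
demographics, pricing, event timing, compliance, …) and a 10,000-iteration
probabilistic sensitivity analysis (beta/gamma moment-matched draws) with
CE-plane and cost-effectiveness acceptability curve outputs.  See
`docs/methods.md` for assumptions and `docs/config_schema.md` for the
config format.

## Worked example

```sh
python examples/base_case.py
```

prints (abridged):

```
                       quantity       sentio         osia   difference
              cost_implantation 20894.610000 21263.610000  -369.000000
                  cost_revision     0.000000  1990.407680 -1990.407680
                   cost_battery   254.991859   553.822643  -298.830784
                     total_cost 43338.211340 51184.477570 -7846.266230
                    total_qalys     8.197328     8.085444     0.111884
               total_life_years    10.786458    10.786458     0.000000

classification: dominant
net monetary benefit at 50,000 AUD/QALY: 13,440 AUD
```

The reference arm is cheaper (the implantation difference is exactly the
device-price difference; revisions and explantations never occur at its
base-case zero rates) and gains ~0.112 QALYs — mostly time spent on rather
than off the device — while life years are identical by construction
(shared mortality).  It therefore *dominates*: no ICER is reported.  The
other examples run the tornado (`examples/tornado.py`), the scenario
catalog (`examples/scenarios.py`), the PSA with CEAC
(`examples/psa_ceac.py`, P(cost-effective at 50,000 AUD/QALY) ≈ 0.99) and
the device-price threshold search (`examples/price_threshold.py`, the ICER
reaches 50,000 AUD/QALY at a device price of about 23,500 AUD).

The same analyses are available from the shell:

```sh
bchicea run-base --params-ref sentio --params-cmp osia --out out/
bchicea run-uncertainty --mode psa --seed 1 --iterations 10000 --out out/
```

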