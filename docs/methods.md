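# Methods

## Model

`bchicea` implements a Markov cohort state-transition model for
bone-conduction hearing implant (BCHI) systems in the Australian healthcare
setting, from a healthcare-system perspective (direct medical costs only).
A cohort of implanted patients moves through four states in 6-month cycles:

- **on BCHI, first implant** — everyone starts here;
- **on BCHI, second implant** — reached through an adverse-event(AE)-driven
  reimplantation, which can happen at most once (no third implant);
- **off BCHI** — permanent exit after explantation surgery;
- **dead** — absorbing; mortality follows age- and sex-specific population
  rates and is identical in every arm (implant status does not affect
  survival).

While on the device, patients can also experience events that do not change
their health state: revision surgery, anticipated reimplantation (scheduled
replacement at end of device life or with progressing hearing loss),
sound-processor (SP) replacement, and two adverse events (soft-tissue
complications and pain).  All per-cycle probabilities are constant over the
horizon.

Within each cycle the order of operations is: death, explantation,
AE-driven reimplantation, then within-state events recorded at the
post-transition on-state occupancy.  Death first reflects that mortality is
independent of implant status; the remaining order is a modelling choice
(the events are near-exclusive at these probabilities, so the ordering
effect is second-order).  The alive fraction is evolved as its own survival
sequence, so two arms sharing a mortality table have bit-identical life
years and the incremental life years are exactly zero.

The second-implant state inherits every first-implant probability except
AE-driven reimplantation (set to zero) — the most conservative continuation
consistent with the one-reimplantation rule.

## Timed recurring events

Anticipated reimplantation and SP replacement run on a *device-age clock*
starting at model entry.  Inter-event times follow a gamma distribution
(lognormal and deterministic point mass are available as options) with the
configured mean (anticipated: 15 y for the electromagnetic-transducer
systems Sentio/Ponto, 10 y for Osia/Baha Attract; SP replacement: 5 y for
all systems) discretised to cycle bins, f_j = F(jΔ) − F((j−1)Δ).  Recurrence
uses the discrete renewal equation m_j = f_j + Σ_{i<j} m_i f_{j−i}; expected
events per cycle are the on-state occupancy times m_j.  Compliance below 1
thins f before the renewal recursion, so a missed replacement also ends the
chain of later replacements.

The coefficient of variation of these distributions is not an observed
quantity; the default CV = 0.35 (shared by both events, overridable per
event) gives a unimodal spread of roughly ±2 SP-replacement years around the
5-year mean, consistent with the motivation of smoothing discrete cost
jumps.  Cost categories driven by these schedules (anticipated
reimplantation, SP replacement, hence total costs) are sensitive to the CV;
quantities independent of it (life years, QALYs, battery/maintenance costs,
the structural zeros) are the ones the acceptance checks pin down.

The device-age clock is *not* reset by an AE-driven reimplantation
(tractability; the event is rare at 0.44–0.55% per cycle).  This slightly
overstates anticipated-reimplantation timing for the few affected patients
and is a documented limitation.

## Mortality

Annual probabilities q(age, sex) come from a life table (bundled fixture or
user-supplied TSV).  Conversion to cycles uses the constant-hazard-in-year
convention p = 1 − (1−q)^Δ; the table row is looked up at floor(model age),
with the sex mix (default 50% female) applied as a weighted average of the
annual probabilities.  Ages beyond the table use the terminal absorbing row.
The bundled table is a synthetic Gompertz–Makeham table calibrated to
published Australian adult mortality summaries (q40 ≈ 0.76/1.34 per 1000
female/male); it is labelled synthetic in its filename and header.  Because
the exact national life-table vintage behind the original analysis is not
fixed, absolute QALY/life-year totals carry a small documented tolerance
(±0.02 QALYs in the acceptance checks); incremental results are almost
insensitive to the vintage.

A `"lifetime"` horizon runs until the cohort's alive fraction falls below
10⁻⁶ or the terminal age is reached.

## Discounting and half-cycle correction

Both costs and QALYs are discounted at 5%/year by default.  Two compounding
conventions are implemented:

- `annual` (default): the discount factor is (1+r)^(−y) with y the whole
  year containing the cycle-start time — the spreadsheet convention of
  updating the factor at year boundaries.  This convention reproduces the
  published deterministic table (discounted life years 10.79, battery and
  maintenance cost categories within ~1%).
- `cycle`: (1+r)^(−t) at the continuous cycle-start time.

With the half-cycle correction on (default), state person-time per cycle is
the trapezoidal mean of start- and end-of-cycle occupancy.  Event costs are
discounted at their cycle's reference time; `event_discount_timing` moves
that reference to the cycle midpoint or end (shifts totals by <1.5% at 5%).

## Costs

Unit costs (AUD, 2024 tariffs) combine into per-procedure bundles: the
implantation bundle (device + surgery + anaesthesia × anaesthetised
fraction + hospitalisation + two audiologist visits and one specialist
follow-up) is charged to the whole cohort at entry, undiscounted.  Revision
repeats the surgical bundle; reimplantation (either kind) adds the device;
explantation omits the follow-up visits; SP replacement is the replacement
processor plus one audiologist visit; each AE costs two specialist
appointments.  Routine maintenance (one annual audiologist appointment,
87.70 AUD per 6-month cycle) and batteries accrue per cycle while on the
device, using the half-cycle-corrected occupancy; the off-BCHI state accrues
no costs.  Battery amounts are taken directly as the per-cycle figures of
the tariff table.  Anaesthesia applies to 100% of procedures for the
transcutaneous systems, 0% for the percutaneous Ponto and 50% for Baha
Attract.

## QALYs

State utilities (Health Utilities Index-derived): on-BCHI 0.76, off-BCHI
0.67 for the pooled population, with conductive/mixed-loss (0.73/0.62) and
single-sided-deafness (0.86/0.84) subgroups selectable per run.  The same
weights apply to all active systems; Baha Attract carries an on-state
decrement (−0.03 pooled; −0.06 / −0.01 by subgroup).

Adverse events subtract per-event disutilities at the event's cycle:

- **pain**: −0.002 QALYs per event, already scaled to a three-day episode
  at source, applied as is;
- **soft tissue**: −0.030 is a health-state *utility decrement* (superficial
  wound infection analogue) and needs an episode duration to become a QALY
  loss.  The default duration is 0.25 years (a three-month episode, i.e.
  −0.0075 QALYs per event), which is what reconciles the published
  incremental QALYs (0.112) with the published maintenance-cost cells;
  treating the full −0.030 as a per-event QALY loss would imply an
  incremental gain of ~0.14.  The duration is a config knob
  (`soft_tissue_duration_years`).

## Sensitivity machinery

**One-way (tornado).** Every parameter with uncertainty moves to
mean ± 1.96·SE (clamped to its domain; SEs default to 10% of the value when
unreported) with a full deterministic rerun at each bound; entries are
ranked by the spread of incremental net monetary benefit at the 50,000
AUD/QALY threshold.  Which parameter ranks first depends on the timing CV
through the device-cost multipliers; the shared on-BCHI utility is always
among the top drivers.

**Scenarios.** A bundled catalog varies one structural assumption at a time:
discount rates (0%, 3.5%, 5/3%), half-cycle correction off, 3- and 12-month
cycles (probabilities rate-converted via p′ = 1 − (1−p)^(Δ′/Δ), per-cycle
costs scaled linearly), horizons of 5/10/20 years and lifetime, cohort ages
30 and 60, single-sex cohorts, subgroup utilities, reference-device prices
of 13,000 and 15,000 AUD, ±20% anticipated-reimplantation timing, 4- and
6-year SP intervals, lognormal timing, excluding anticipated reimplantation,
doubled audiologist visits, 80% replacement compliance, and ±5%
hospitalisation price inflation.  Alternative published transition
probabilities are supported through override maps but no alternative value
set is bundled.  Reports show signed deltas *and* percent changes, since
percent changes of a negative incremental cost are ambiguous on their own.
A lower discount rate raises incremental QALYs (late-accruing gains are
up-weighted): +13.0% at 3.5% and +53.4% at 0% against the 5% base case.

**PSA.** Monte-Carlo parameter uncertainty (default 10,000 iterations):
beta distributions moment-matched to (mean, SE) for probabilities and
utilities (on the magnitude for decrements), gamma for costs.  Parameters
with zero base-case events, zero SE, or a boundary mean stay fixed;
event-timing means stay at base case (their uncertainty is structural and
covered by scenarios).  If an SE is too large for beta moment matching
(variance ≥ m(1−m)) the variance is clamped to 95% of the feasible maximum
and a warning is attached to the output.  Utilities shared by both arms are
drawn once per iteration and applied to both (they estimate the same
quantity — the one deliberate cross-arm coupling, flagged in the output
metadata); everything else is independent per arm.  Draws come from
counter-based substreams keyed by parameter label, so adding a parameter
never perturbs the others' draws and a seed fully reproduces the output.

**Price threshold.** Bisection on the reference arm's device acquisition
price until the ICER is within 0.5 AUD/QALY of a target, searching the
trade-off region above the dominance boundary, with every candidate
verified by a full deterministic rerun.

## Synthetic test data

`synthetic_parameter_set(seed)` generates valid random parameter sets
(probabilities in [0, 0.1], utilities in [0.5, 1], plausible AUD costs) for
property tests; `synthetic_life_table` builds Gompertz–Makeham tables for
mortality-dependent checks.  The test suite also contains an
individual-level microsimulation that pushes tens of thousands of simulated
patients through the same discrete per-cycle dynamics, drawing device-clock
gaps from the same discretised distributions: the cohort trace is the exact
expectation of that process, and equality within three Monte-Carlo standard
errors is enforced for discounted costs and QALYs.  What these tests do not
exercise: real registry event rates, time-varying risks, correlated
parameters, patient heterogeneity — all outside the cohort model by design.

## Numerical notes and known limitations

- Occupancy conservation is checked every cycle at 10⁻⁸; the renewal
  recursion is O(n²) in cycles (n ≤ ~140 for a lifetime run).
- A deterministic timing family with an off-grid mean assigns the event to
  the cycle containing the mean.
- The published AE-driven-reimplantation cost cells imply a discounted
  at-risk exposure inconsistent with the explantation/revision cells under
  any within-cycle ordering we tried; the model follows the stated state
  structure, and those two categories differ from the published table by a
  few hundred AUD.
- Problem sizes used throughout (30–122 cycles, 10,000 PSA iterations,
  30,000 microsimulated patients in tests) were chosen as the standard
  sizes for desk-scale cohort analyses of this type.
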