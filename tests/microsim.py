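"""Individual-level Monte-Carlo oracle for the cohort engine.

Simulates patients one by one through the same discrete per-cycle dynamics
the cohort model uses (death → explantation → AE-driven reimplantation →
within-state events), drawing device-clock event gaps from the same
discretised inter-event distribution the renewal equation uses.  The cohort
trace is the exact expectation of this process, so discounted totals must
agree within Monte-Carlo error.  Test-only code: the production engine is
the cohort model.
"""

from __future__ import annotations

import numpy as np

from bchicea.economics import _event_bundles
from bchicea.engine import discount_factors, event_schedule, n_cycles


def _renewal_counts(first: np.ndarray, n_patients: int, rng) -> np.ndarray:
    """Per-patient event counts by cycle for a (possibly defective) renewal
    chain whose gap distribution is ``first`` (tail mass = chain stops)."""
    n = first.size
    cum = np.cumsum(np.append(first, max(0.0, 1.0 - first.sum())))
    cum[-1] = 1.0
    counts = np.zeros((n_patients, n), dtype=np.int16)
    clock = np.zeros(n_patients, dtype=np.int64)
    active = np.ones(n_patients, dtype=bool)
    while active.any():
        rows = np.flatnonzero(active)
        gaps = np.searchsorted(cum, rng.random(rows.size), side="right")  # 0..n
        t_new = clock[rows] + gaps + 1
        ok = (gaps < n) & (t_new <= n)
        counts[rows[ok], t_new[ok] - 1] += 1
        clock[rows[ok]] = t_new[ok]
        active[rows[~ok]] = False
    return counts


def microsimulate(params, settings, table, n_patients: int, seed: int) -> dict:
    """Mean discounted cost and QALYs per patient, with standard errors."""
    rng = np.random.default_rng(seed)
    n = n_cycles(settings, table)
    dt = settings.cycle_length
    tp = params.transitions
    q_mix = table.mixed_annual(settings.sex_mix)
    p_die = np.array(
        [
            1.0 - (1.0 - q_mix[min(int((settings.start_age + (j - 1) * dt)), table.terminal_age)]) ** dt
            for j in range(1, n + 1)
        ]
    )

    on1 = np.ones(n_patients, dtype=bool)
    on2 = np.zeros(n_patients, dtype=bool)
    off = np.zeros(n_patients, dtype=bool)
    on_end = np.zeros((n_patients, n + 1), dtype=bool)
    off_end = np.zeros((n_patients, n + 1), dtype=bool)
    on_end[:, 0] = True
    expl_cycle = np.zeros((n_patients, n), dtype=bool)
    reimpl_cycle = np.zeros((n_patients, n), dtype=bool)
    rev = np.zeros((n_patients, n), dtype=bool)
    soft = np.zeros((n_patients, n), dtype=bool)
    pain = np.zeros((n_patients, n), dtype=bool)

    for j in range(n):
        alive = on1 | on2 | off
        dies = alive & (rng.random(n_patients) < p_die[j])
        on1 &= ~dies
        on2 &= ~dies
        off &= ~dies
        on = on1 | on2
        expl = on & (rng.random(n_patients) < tp.explantation)
        off |= expl
        on1 &= ~expl
        on2 &= ~expl
        moved = on1 & (rng.random(n_patients) < tp.ae_reimplantation)
        on1 &= ~moved
        on2 |= moved
        on = on1 | on2
        expl_cycle[:, j] = expl
        reimpl_cycle[:, j] = moved
        rev[:, j] = on & (rng.random(n_patients) < tp.revision)
        soft[:, j] = on & (rng.random(n_patients) < tp.soft_tissue)
        pain[:, j] = on & (rng.random(n_patients) < tp.pain)
        on_end[:, j + 1] = on
        off_end[:, j + 1] = off

    sched_ar = event_schedule(params.timing, "anticipated_reimplantation", settings,
                              n=n, table=table)
    sched_sp = event_schedule(params.timing, "sp_replacement", settings, n=n, table=table)
    anticipated = (
        _renewal_counts(sched_ar.first, n_patients, rng) * on_end[:, 1:]
        if params.timing.anticipated_enabled
        else np.zeros((n_patients, n))
    )
    sp = _renewal_counts(sched_sp.first, n_patients, rng) * on_end[:, 1:]

    b = _event_bundles(params)
    d_ev = discount_factors(settings.discount_rate_costs, n, settings,
                            timing=settings.event_discount_timing)
    d_cost = discount_factors(settings.discount_rate_costs, n, settings)
    d_q = discount_factors(settings.discount_rate_qalys, n, settings)

    on_f, off_f = on_end.astype(float), off_end.astype(float)
    if settings.half_cycle_correction:
        mean_on = 0.5 * (on_f[:, :-1] + on_f[:, 1:])
        mean_off = 0.5 * (off_f[:, :-1] + off_f[:, 1:])
    else:
        mean_on = on_f[:, 1:]
        mean_off = off_f[:, 1:]

    cost = (
        b["implantation"]
        + (rev * d_ev).sum(axis=1) * b["revision"]
        + ((anticipated + reimpl_cycle) * d_ev).sum(axis=1) * b["reimplantation"]
        + (expl_cycle * d_ev).sum(axis=1) * b["explantation"]
        + (sp * d_ev).sum(axis=1) * b["sp_replacement"]
        + ((soft.astype(int) + pain.astype(int)) * d_ev).sum(axis=1)
        * params.costs.ae_management_per_event
        + (mean_on * d_cost).sum(axis=1)
        * (params.costs.hcru_per_cycle + params.costs.battery_per_cycle)
    )

    u = params.utilities
    u_on, u_off, dec = u.for_subgroup(settings.utility_subgroup)
    qalys = (
        dt * ((u_on + dec) * (mean_on * d_q).sum(axis=1) + u_off * (mean_off * d_q).sum(axis=1))
        + (soft * d_q).sum(axis=1) * u.soft_tissue_decrement * u.soft_tissue_duration_years
        + (pain * d_q).sum(axis=1) * u.pain_decrement
    )

    return {
        "mean_cost": float(cost.mean()),
        "se_cost": float(cost.std(ddof=1) / np.sqrt(n_patients)),
        "mean_qalys": float(qalys.mean()),
        "se_qalys": float(qalys.std(ddof=1) / np.sqrt(n_patients)),
    }
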