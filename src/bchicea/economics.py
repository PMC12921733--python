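"""Discounted costs, QALYs and life years from a cohort trace, and the
incremental comparison between two arms (ICER, net monetary benefit,
dominance classification).

Cost bundles
------------
* implantation (cycle 0, full cohort, undiscounted): device + surgery +
  anaesthesia × anaesthetised fraction + hospitalisation + post-surgery
  visits (two audiologist appointments and one surgical follow-up);
* revision = surgery + anaesthesia × fraction + hospitalisation +
  post-surgery visits;
* reimplantation (AE-driven or anticipated) = revision bundle + device;
* explantation = surgery + anaesthesia × fraction + hospitalisation
  (no follow-up visits);
* SP replacement = replacement sound processor + one audiologist visit;
* adverse events = per-event management cost;
* routine healthcare use and batteries accrue per cycle while on the device.

Event costs are discounted at the event's cycle (start-of-cycle reference by
default); continuously accruing categories use the half-cycle-corrected
occupancy.  QALYs combine state utilities with per-event disutilities.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .engine import CohortTrace, discount_factors, occupancy_integral, run_cohort
from .lifetables import LifeTable
from .parameters import ComparatorParameterSet, ModelSettings

__all__ = [
    "COST_CATEGORIES",
    "EconomicResult",
    "Classification",
    "IncrementalResult",
    "accrue_costs",
    "accrue_qalys",
    "evaluate",
    "compare",
    "run_comparison",
]

COST_CATEGORIES = (
    "implantation",
    "revision",
    "anticipated_reimplantation",
    "ae_reimplantation",
    "explantation",
    "sp_replacement",
    "hcru",
    "battery",
    "ae_management",
)

_EQUIV_TOL = 1e-9


@dataclass(frozen=True)
class EconomicResult:
    """Discounted per-patient results for one arm (deterministic table shape)."""

    name: str
    costs: dict[str, float]
    total_cost: float
    total_qalys: float
    total_life_years: float

    def __post_init__(self):
        if abs(self.total_cost - sum(self.costs.values())) > 1e-6:
            raise ValueError("total_cost does not equal the category sum")


class Classification(str, Enum):
    DOMINANT = "dominant"  # cheaper and more effective
    DOMINATED = "dominated"
    TRADEOFF_NE = "tradeoff_ne"  # more costly, more effective
    TRADEOFF_SW = "tradeoff_sw"  # cheaper, less effective
    EQUIVALENT = "equivalent"


@dataclass(frozen=True)
class IncrementalResult:
    """Reference minus comparator deltas and their interpretation."""

    delta_cost: float
    delta_qalys: float
    delta_life_years: float
    icer: float | None
    nmb: float
    classification: Classification
    wtp: float


def _event_bundles(params: ComparatorParameterSet) -> dict[str, float]:
    c = params.costs
    surgery = c.surgery_implantation + c.anaesthesia * c.anaesthesia_fraction + c.hospitalisation
    follow_up = c.post_surgery_audiologist_bundle + c.post_surgery_specialist
    revision = surgery + follow_up
    return {
        "implantation": c.device_acquisition + revision,
        "revision": revision,
        "reimplantation": revision + c.device_acquisition,
        "explantation": surgery,  # no follow-up visits after explantation
        "sp_replacement": c.sp_replacement_device + c.sp_replacement_visit,
    }


def accrue_costs(
    trace: CohortTrace, params: ComparatorParameterSet, settings: ModelSettings
) -> dict[str, float]:
    """Discounted cost per category, AUD per initially implanted patient."""
    bundles = _event_bundles(params)
    disc_ev = discount_factors(
        settings.discount_rate_costs, trace.n, settings, timing=settings.event_discount_timing
    )
    ev = trace.events
    costs = {
        "implantation": bundles["implantation"],  # cycle 0, undiscounted
        "revision": float(np.sum(disc_ev * ev["revisions"])) * bundles["revision"],
        "anticipated_reimplantation": float(
            np.sum(disc_ev * ev["anticipated_reimplantations"])
        )
        * bundles["reimplantation"],
        "ae_reimplantation": float(np.sum(disc_ev * ev["ae_reimplantations"]))
        * bundles["reimplantation"],
        "explantation": float(np.sum(disc_ev * ev["explantations"])) * bundles["explantation"],
        "sp_replacement": float(np.sum(disc_ev * ev["sp_replacements"]))
        * bundles["sp_replacement"],
        "ae_management": float(
            np.sum(disc_ev * (ev["soft_tissue_events"] + ev["pain_events"]))
        )
        * params.costs.ae_management_per_event,
    }
    # continuously accruing while on the device: per-cycle sums use the
    # half-cycle-corrected occupancy (units: cycles, not years)
    on_cycles = occupancy_integral(
        trace, "on", settings.discount_rate_costs, settings
    ) / settings.cycle_length
    costs["hcru"] = on_cycles * params.costs.hcru_per_cycle
    costs["battery"] = on_cycles * params.costs.battery_per_cycle
    return costs


def accrue_qalys(
    trace: CohortTrace, params: ComparatorParameterSet, settings: ModelSettings
) -> float:
    """Total discounted QALYs: state utilities plus per-event disutilities.

    The soft-tissue disutility is a utility decrement sustained for the
    configured episode duration; the pain disutility is a per-event QALY
    loss already scaled to its episode length at source.
    """
    u = params.utilities
    u_on, u_off, decrement = u.for_subgroup(settings.utility_subgroup)
    u_on_eff = u_on + decrement
    r = settings.discount_rate_qalys
    state = u_on_eff * occupancy_integral(trace, "on", r, settings) + u_off * occupancy_integral(
        trace, "off", r, settings
    )
    disc = discount_factors(r, trace.n, settings)
    soft_loss_per_event = u.soft_tissue_decrement * u.soft_tissue_duration_years
    events = float(
        np.sum(
            disc
            * (
                trace.events["soft_tissue_events"] * soft_loss_per_event
                + trace.events["pain_events"] * u.pain_decrement
            )
        )
    )
    return state + events


def evaluate(
    params: ComparatorParameterSet,
    settings: ModelSettings,
    table: LifeTable,
    trace: CohortTrace | None = None,
    schedules=None,
) -> EconomicResult:
    """Run one arm end to end: trace, cost accrual, QALYs, life years."""
    if trace is None:
        trace = run_cohort(params, settings, table, schedules=schedules)
    costs = accrue_costs(trace, params, settings)
    return EconomicResult(
        name=params.name,
        costs=costs,
        total_cost=sum(costs.values()),
        total_qalys=accrue_qalys(trace, params, settings),
        total_life_years=occupancy_integral(
            trace, "alive", settings.discount_rate_qalys, settings
        ),
    )


def compare(
    reference: EconomicResult, comparator: EconomicResult, wtp: float
) -> IncrementalResult:
    """Incremental analysis of the reference arm against the comparator.

    Deltas are reference − comparator.  The ICER is reported only in the
    two trade-off quadrants; dominance needs no ratio.
    """
    d_cost = reference.total_cost - comparator.total_cost
    d_q = reference.total_qalys - comparator.total_qalys
    d_ly = reference.total_life_years - comparator.total_life_years
    nmb = wtp * d_q - d_cost
    if abs(d_cost) <= _EQUIV_TOL and abs(d_q) <= _EQUIV_TOL:
        cls, icer = Classification.EQUIVALENT, None
    elif d_cost <= 0 and d_q >= 0:
        cls, icer = Classification.DOMINANT, None
    elif d_cost >= 0 and d_q <= 0:
        cls, icer = Classification.DOMINATED, None
    else:
        cls = Classification.TRADEOFF_NE if d_q > 0 else Classification.TRADEOFF_SW
        icer = d_cost / d_q
    return IncrementalResult(
        delta_cost=d_cost,
        delta_qalys=d_q,
        delta_life_years=d_ly,
        icer=icer,
        nmb=nmb,
        classification=cls,
        wtp=wtp,
    )


def run_comparison(
    reference: ComparatorParameterSet,
    comparator: ComparatorParameterSet,
    settings: ModelSettings,
    table: LifeTable,
) -> tuple[EconomicResult, EconomicResult, IncrementalResult]:
    """Evaluate both arms with shared settings/mortality and compare them."""
    res_ref = evaluate(reference, settings, table)
    res_cmp = evaluate(comparator, settings, table)
    return res_ref, res_cmp, compare(res_ref, res_cmp, settings.wtp_threshold)
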