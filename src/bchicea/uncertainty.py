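"""Sensitivity machinery: one-way (tornado) analysis, the deterministic
scenario catalog, probabilistic sensitivity analysis (PSA) with CE-plane and
cost-effectiveness acceptability curve (CEAC) outputs, and a device-price
threshold search.

Parameter uncertainty follows the usual health-economics conventions: 95%
intervals are mean ± 1.96·SE clamped to the valid domain; missing SEs fall
back to 10% of the parameter value; the PSA assigns moment-matched beta
distributions to utilities and event probabilities and gamma distributions
to costs, holding parameters with zero base-case events fixed.  Utilities
shared between two active devices are drawn once per iteration and applied
to both arms (they estimate the same quantity); every other parameter is
drawn independently per arm.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Optional, Sequence

import numpy as np

from .economics import IncrementalResult, compare, evaluate
from .engine import event_schedule, n_cycles, rescale_probability
from .lifetables import LifeTable
from .parameters import (
    ComparatorParameterSet,
    ModelSettings,
    apply_overrides,
    apply_settings_overrides,
)

__all__ = [
    "ParameterRef",
    "TornadoEntry",
    "ScenarioSpec",
    "ScenarioResult",
    "PSAOutput",
    "parameter_catalog",
    "one_way_sa",
    "bundled_scenarios",
    "run_scenarios",
    "adapt_cycle_length",
    "psa",
    "ceac",
    "price_threshold",
]

_Z95 = 1.959963984540054  # standard normal 97.5% quantile

_PROB_FIELDS = ("explantation", "revision", "ae_reimplantation", "soft_tissue", "pain")
_COST_FIELDS = (
    "device_acquisition",
    "sp_replacement_device",
    "surgery_implantation",
    "anaesthesia",
    "hospitalisation",
    "post_surgery_audiologist_bundle",
    "post_surgery_specialist",
    "sp_replacement_visit",
    "ae_management_per_event",
    "hcru_per_cycle",
    "battery_per_cycle",
)
_SE_FALLBACK = 0.10  # of the parameter value, when no SE is reported


@dataclass(frozen=True)
class ParameterRef:
    """One stochastic scalar input: where it lives and its uncertainty.

    ``arm`` is ``"ref"``, ``"cmp"`` or ``"shared"`` (drawn once, applied to
    both arms).  ``kind`` drives the PSA family and the clamping domain:
    probability/utility → beta on [0, 1], decrement → beta on the magnitude,
    cost/timing → gamma on [0, ∞).
    """

    arm: str
    path: str
    kind: str
    mean: float
    se: float

    @property
    def label(self) -> str:
        return f"{self.arm}:{self.path}"

    def clamp(self, value: float) -> float:
        if self.kind in ("probability", "utility"):
            return float(min(1.0, max(0.0, value)))
        if self.kind == "decrement":
            return float(min(0.0, max(-1.0, value)))
        return float(max(1e-9 if self.kind == "timing" else 0.0, value))


def _utility_refs(
    ref: ComparatorParameterSet, cmp_: ComparatorParameterSet
) -> list[ParameterRef]:
    out = []
    shared_pairs = [
        ("utilities.on_bchi", "utility", ref.utilities.on_bchi, ref.utilities.on_bchi_se,
         cmp_.utilities.on_bchi),
        ("utilities.off_bchi", "utility", ref.utilities.off_bchi, ref.utilities.off_bchi_se,
         cmp_.utilities.off_bchi),
        ("utilities.soft_tissue_decrement", "decrement", ref.utilities.soft_tissue_decrement,
         ref.utilities.soft_tissue_decrement_se, cmp_.utilities.soft_tissue_decrement),
        ("utilities.pain_decrement", "decrement", ref.utilities.pain_decrement,
         ref.utilities.pain_decrement_se, cmp_.utilities.pain_decrement),
    ]
    for path, kind, mean, se, cmp_val in shared_pairs:
        if mean == cmp_val:
            out.append(ParameterRef("shared", path, kind, mean, se))
        else:
            out.append(ParameterRef("ref", path, kind, mean, se))
            out.append(ParameterRef("cmp", path, kind, cmp_val, se))
    for arm, params in (("ref", ref), ("cmp", cmp_)):
        dec = params.utilities.on_state_decrement
        if dec != 0.0:
            out.append(
                ParameterRef(arm, "utilities.on_state_decrement", "decrement", dec,
                             _SE_FALLBACK * abs(dec))
            )
    return out


def parameter_catalog(
    ref: ComparatorParameterSet,
    cmp_: ComparatorParameterSet,
    *,
    include_timing: bool = True,
) -> list[ParameterRef]:
    """Default list of stochastic inputs for a two-arm comparison.

    Transition/adverse-event probabilities use their reported SEs; costs use
    the 10% fallback; utilities shared by both arms appear once as shared
    entries.  Timing means are included for the tornado but excluded from
    the PSA (set ``include_timing=False``).
    """
    refs: list[ParameterRef] = []
    for arm, params in (("ref", ref), ("cmp", cmp_)):
        tp = params.transitions
        for f in _PROB_FIELDS:
            refs.append(
                ParameterRef(arm, f"transitions.{f}", "probability",
                             getattr(tp, f), getattr(tp, f"{f}_se"))
            )
        for f in _COST_FIELDS:
            v = getattr(params.costs, f)
            refs.append(ParameterRef(arm, f"costs.{f}", "cost", v, _SE_FALLBACK * v))
        refs.append(
            ParameterRef(arm, "costs.anaesthesia_fraction", "probability",
                         params.costs.anaesthesia_fraction,
                         _SE_FALLBACK * params.costs.anaesthesia_fraction)
        )
        if include_timing:
            t = params.timing
            refs.append(
                ParameterRef(arm, "timing.anticipated_reimplantation_mean", "timing",
                             t.anticipated_reimplantation_mean,
                             _SE_FALLBACK * t.anticipated_reimplantation_mean)
            )
            refs.append(
                ParameterRef(arm, "timing.sp_replacement_mean", "timing",
                             t.sp_replacement_mean, _SE_FALLBACK * t.sp_replacement_mean)
            )
    refs.extend(_utility_refs(ref, cmp_))
    return refs


# ---------------------------------------------------------------------------
# one-way sensitivity analysis


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low_input: float
    high_input: float
    nmb_low: float
    nmb_high: float

    @property
    def range(self) -> float:
        return abs(self.nmb_high - self.nmb_low)


def _arms_with(
    ref: ComparatorParameterSet,
    cmp_: ComparatorParameterSet,
    pref: ParameterRef,
    value: float,
) -> tuple[ComparatorParameterSet, ComparatorParameterSet]:
    if pref.arm in ("ref", "shared"):
        ref = apply_overrides(ref, {pref.path: value})
    if pref.arm in ("cmp", "shared"):
        cmp_ = apply_overrides(cmp_, {pref.path: value})
    return ref, cmp_


def _nmb(
    ref: ComparatorParameterSet,
    cmp_: ComparatorParameterSet,
    settings: ModelSettings,
    table: LifeTable,
) -> float:
    res_r = evaluate(ref, settings, table)
    res_c = evaluate(cmp_, settings, table)
    return compare(res_r, res_c, settings.wtp_threshold).nmb


def one_way_sa(
    ref: ComparatorParameterSet,
    cmp_: ComparatorParameterSet,
    settings: ModelSettings,
    table: LifeTable,
    parameters: Optional[Sequence[ParameterRef]] = None,
) -> list[TornadoEntry]:
    """Tornado analysis: incremental NMB at each parameter's 95% CI bounds.

    Each parameter is varied independently at mean ± 1.96·SE (clamped to its
    valid domain) with a full deterministic rerun at each bound; entries are
    sorted by descending NMB range.
    """
    if parameters is None:
        parameters = parameter_catalog(ref, cmp_)
    if not parameters:
        raise ValueError("empty parameter list")
    entries = []
    for pref in parameters:
        lo = pref.clamp(pref.mean - _Z95 * pref.se)
        hi = pref.clamp(pref.mean + _Z95 * pref.se)
        nmb_lo = _nmb(*_arms_with(ref, cmp_, pref, lo), settings, table)
        nmb_hi = _nmb(*_arms_with(ref, cmp_, pref, hi), settings, table)
        entries.append(TornadoEntry(pref.label, lo, hi, nmb_lo, nmb_hi))
    return sorted(entries, key=lambda e: e.range, reverse=True)


# ---------------------------------------------------------------------------
# scenario catalog


@dataclass(frozen=True)
class ScenarioSpec:
    """A named deterministic re-run with structural or parameter overrides.

    ``both_overrides`` and ``both_scalers`` apply to both arms (absolute
    values and multiplicative factors respectively); ``ref_overrides`` /
    ``cmp_overrides`` are arm-specific dotted-path maps.
    """

    name: str
    settings_overrides: Mapping = dc_field(default_factory=dict)
    ref_overrides: Mapping = dc_field(default_factory=dict)
    cmp_overrides: Mapping = dc_field(default_factory=dict)
    both_overrides: Mapping = dc_field(default_factory=dict)
    both_scalers: Mapping = dc_field(default_factory=dict)


@dataclass(frozen=True)
class ScenarioResult:
    name: str
    incremental: IncrementalResult
    pct_change_cost: float
    pct_change_qalys: float


def adapt_cycle_length(
    params: ComparatorParameterSet, from_cycle: float, to_cycle: float
) -> ComparatorParameterSet:
    """Rate-convert per-cycle probabilities and per-cycle costs to a new
    cycle length (p′ = 1 − (1−p)^(Δ′/Δ); per-cycle amounts scale linearly)."""
    if from_cycle == to_cycle:
        return params
    overrides: dict[str, float] = {}
    for f in _PROB_FIELDS:
        p = getattr(params.transitions, f)
        p2 = rescale_probability(p, from_cycle, to_cycle)
        overrides[f"transitions.{f}"] = p2
        se = getattr(params.transitions, f"{f}_se")
        overrides[f"transitions.{f}_se"] = se * (p2 / p) if p > 0 else se * to_cycle / from_cycle
    scale = to_cycle / from_cycle
    overrides["costs.hcru_per_cycle"] = params.costs.hcru_per_cycle * scale
    overrides["costs.battery_per_cycle"] = params.costs.battery_per_cycle * scale
    return apply_overrides(params, overrides)


def _resolve_scenario(
    spec: ScenarioSpec,
    ref: ComparatorParameterSet,
    cmp_: ComparatorParameterSet,
    settings: ModelSettings,
) -> tuple[ComparatorParameterSet, ComparatorParameterSet, ModelSettings]:
    try:
        new_settings = apply_settings_overrides(settings, spec.settings_overrides)
        arms = []
        for params, arm_overrides in ((ref, spec.ref_overrides), (cmp_, spec.cmp_overrides)):
            merged = dict(spec.both_overrides)
            merged.update(arm_overrides)
            scaled = {
                path: factor * _get_path(params, path)
                for path, factor in spec.both_scalers.items()
            }
            merged.update(scaled)
            params = apply_overrides(params, merged) if merged else params
            if new_settings.cycle_length != settings.cycle_length:
                params = adapt_cycle_length(
                    params, settings.cycle_length, new_settings.cycle_length
                )
            arms.append(params)
        return arms[0], arms[1], new_settings
    except (KeyError, ValueError) as exc:
        raise ValueError(f"scenario {spec.name!r} is not resolvable: {exc}") from exc


def _get_path(params: ComparatorParameterSet, path: str):
    node = params
    for key in path.split("."):
        node = getattr(node, key)
    return node


def run_scenarios(
    catalog: Sequence[ScenarioSpec],
    ref: ComparatorParameterSet,
    cmp_: ComparatorParameterSet,
    settings: ModelSettings,
    table: LifeTable,
) -> list[ScenarioResult]:
    """Deterministic rerun of each scenario, with percent changes of the
    incremental cost and QALYs relative to the base case."""
    base_r = evaluate(ref, settings, table)
    base_c = evaluate(cmp_, settings, table)
    base = compare(base_r, base_c, settings.wtp_threshold)
    results = []
    for spec in catalog:
        s_ref, s_cmp, s_settings = _resolve_scenario(spec, ref, cmp_, settings)
        inc = compare(
            evaluate(s_ref, s_settings, table),
            evaluate(s_cmp, s_settings, table),
            s_settings.wtp_threshold,
        )
        results.append(
            ScenarioResult(
                name=spec.name,
                incremental=inc,
                pct_change_cost=_pct(inc.delta_cost, base.delta_cost),
                pct_change_qalys=_pct(inc.delta_qalys, base.delta_qalys),
            )
        )
    return results


def _pct(new: float, base: float) -> float:
    if base == 0:
        return float("nan") if new != 0 else 0.0
    return 100.0 * (new - base) / base


def bundled_scenarios() -> list[ScenarioSpec]:
    """The packaged deterministic scenario catalog.

    Covers discounting and cycle-correction variants, cycle length, time
    horizon, cohort demographics, subgroup utilities, reference-device
    pricing, event-timing variations (including the lognormal family and
    excluding anticipated reimplantation), audiologist-visit frequency,
    replacement compliance and hospitalisation price-inflation variants.
    """
    S = ScenarioSpec
    return [
        S("discount_0pct", {"discount_rate_costs": 0.0, "discount_rate_qalys": 0.0}),
        S("discount_3.5pct", {"discount_rate_costs": 0.035, "discount_rate_qalys": 0.035}),
        S("discount_costs5_qalys3", {"discount_rate_costs": 0.05, "discount_rate_qalys": 0.03}),
        S("no_half_cycle_correction", {"half_cycle_correction": False}),
        S("cycle_3_months", {"cycle_length": 0.25}),
        S("cycle_12_months", {"cycle_length": 1.0}),
        S("horizon_5y", {"horizon": 5.0}),
        S("horizon_10y", {"horizon": 10.0}),
        S("horizon_20y", {"horizon": 20.0}),
        S("horizon_lifetime", {"horizon": "lifetime"}),
        S("younger_cohort_30y", {"start_age": 30.0}),
        S("older_cohort_60y", {"start_age": 60.0}),
        S("all_male", {"sex_mix": 0.0}),
        S("all_female", {"sex_mix": 1.0}),
        S("utilities_chl_mhl", {"utility_subgroup": "chl_mhl"}),
        S("utilities_ssd", {"utility_subgroup": "ssd"}),
        S("ref_device_price_13000", ref_overrides={"costs.device_acquisition": 13_000.0}),
        S("ref_device_price_15000", ref_overrides={"costs.device_acquisition": 15_000.0}),
        S("anticipated_timing_minus20pct",
          both_scalers={"timing.anticipated_reimplantation_mean": 0.8}),
        S("anticipated_timing_plus20pct",
          both_scalers={"timing.anticipated_reimplantation_mean": 1.2}),
        S("sp_interval_4y", both_overrides={"timing.sp_replacement_mean": 4.0}),
        S("sp_interval_6y", both_overrides={"timing.sp_replacement_mean": 6.0}),
        S("lognormal_timing", both_overrides={"timing.distribution_family": "lognormal"}),
        S("no_anticipated_reimplantation",
          both_overrides={"timing.anticipated_enabled": False}),
        S("audiologist_visits_2_per_year", both_scalers={"costs.hcru_per_cycle": 2.0}),
        S("replacement_compliance_80pct",
          both_overrides={"timing.compliance_anticipated": 0.8, "timing.compliance_sp": 0.8}),
        S("hospitalisation_cpi_minus5pct", both_scalers={"costs.hospitalisation": 0.95}),
        S("hospitalisation_cpi_plus5pct", both_scalers={"costs.hospitalisation": 1.05}),
    ]


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis


@dataclass
class PSAOutput:
    """Per-iteration incremental results and their summaries.

    ``delta_cost``/``delta_qalys`` are reference − comparator per iteration.
    Quadrant shares classify iterations on the CE plane (zero deltas are
    counted with the favourable side and have measure zero in practice).
    """

    seed: int
    n_iterations: int
    delta_cost: np.ndarray
    delta_qalys: np.ndarray
    mean_cost: dict[str, float]
    mean_qalys: dict[str, float]
    quadrant_shares: dict[str, float]
    wtp_grid: np.ndarray
    prob_cost_effective: np.ndarray
    warnings: list[str] = dc_field(default_factory=list)
    metadata: dict = dc_field(default_factory=dict)

    def probability_cost_effective(self, wtp: float) -> float:
        nmb = wtp * self.delta_qalys - self.delta_cost
        return float(np.mean(nmb >= 0.0))


def _param_rng(seed: int, label: str) -> np.random.Generator:
    # counter-based substream keyed by the parameter label: adding or
    # removing a parameter does not perturb the draws of the others
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % 2**31, zlib.crc32(label.encode())])
    )


def _draw(pref: ParameterRef, n: int, seed: int, warnings: list[str]) -> np.ndarray:
    mean, se = pref.mean, pref.se
    rng = _param_rng(seed, pref.label)
    if pref.kind in ("probability", "utility", "decrement"):
        m = abs(mean)
        if m <= 0.0 or m >= 1.0:
            # boundary mean: no beta with this support can vary, keep fixed
            return np.full(n, mean)
        var = se**2
        if var >= m * (1 - m):
            # beta moment matching infeasible; clamp the variance and log it
            var = 0.95 * m * (1 - m)
            warnings.append(
                f"{pref.label}: SE too large for beta moment matching; variance clamped"
            )
        common = m * (1 - m) / var - 1.0
        draws = rng.beta(m * common, (1 - m) * common, size=n)
        return -draws if pref.kind == "decrement" or mean < 0 else draws
    # costs (and any other non-negative scalar): gamma moment matching
    shape = mean**2 / se**2
    return rng.gamma(shape, se**2 / mean, size=n)


def psa(
    ref: ComparatorParameterSet,
    cmp_: ComparatorParameterSet,
    settings: ModelSettings,
    table: LifeTable,
    n_iterations: int = 10_000,
    seed: int = 1,
    wtp_grid: Optional[np.ndarray] = None,
    parameters: Optional[Sequence[ParameterRef]] = None,
) -> PSAOutput:
    """Monte-Carlo parameter uncertainty propagation.

    Beta distributions (moment-matched) for utilities and event
    probabilities, gamma for costs; parameters with a zero base-case mean or
    zero SE stay fixed; event-timing means stay at base case (their
    uncertainty is structural and explored in scenarios).  Shared utilities
    are drawn once per iteration for both arms; all other draws are
    independent per parameter and per arm, from counter-based substreams of
    ``seed``.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be at least 1")
    if wtp_grid is None:
        wtp_grid = np.arange(0.0, 100_001.0, 1_000.0)
    warnings: list[str] = []
    if parameters is None:
        parameters = parameter_catalog(ref, cmp_, include_timing=False)
    # zero base-case means (no observed events) and zero SEs stay fixed
    catalog = [p for p in parameters if p.mean != 0.0 and p.se > 0.0]
    draws = {p.label: _draw(p, n_iterations, seed, warnings) for p in catalog}

    base = {"ref": ref, "cmp": cmp_}
    # per-arm overrides per iteration, as {arm: {path: draws array}}
    per_arm: dict[str, dict[str, np.ndarray]] = {"ref": {}, "cmp": {}}
    for p in catalog:
        arms = ("ref", "cmp") if p.arm == "shared" else (p.arm,)
        for arm in arms:
            per_arm[arm][p.path] = draws[p.label]

    # timing is fixed in the PSA: prebuild the renewal schedules per arm
    n_cyc = n_cycles(settings, table)
    totals = {arm: {"cost": np.empty(n_iterations), "qalys": np.empty(n_iterations)}
              for arm in base}
    for arm, params in base.items():
        schedules = (
            event_schedule(params.timing, "anticipated_reimplantation", settings,
                           n=n_cyc, table=table),
            event_schedule(params.timing, "sp_replacement", settings, n=n_cyc, table=table),
        )
        paths = per_arm[arm]
        for i in range(n_iterations):
            iter_params = (
                _fast_override(params, {p: v[i] for p, v in paths.items()})
                if paths
                else params
            )
            res = evaluate(iter_params, settings, table, schedules=schedules)
            totals[arm]["cost"][i] = res.total_cost
            totals[arm]["qalys"][i] = res.total_qalys

    d_cost = totals["ref"]["cost"] - totals["cmp"]["cost"]
    d_q = totals["ref"]["qalys"] - totals["cmp"]["qalys"]
    shares = {
        "dominant": float(np.mean((d_cost <= 0) & (d_q >= 0))),
        "more_costly_more_effective": float(np.mean((d_cost > 0) & (d_q >= 0))),
        "less_costly_less_effective": float(np.mean((d_cost <= 0) & (d_q < 0))),
        "dominated": float(np.mean((d_cost > 0) & (d_q < 0))),
    }
    prob = np.array([np.mean(l * d_q - d_cost >= 0.0) for l in wtp_grid])
    return PSAOutput(
        seed=seed,
        n_iterations=n_iterations,
        delta_cost=d_cost,
        delta_qalys=d_q,
        mean_cost={ref.name: float(totals["ref"]["cost"].mean()),
                   cmp_.name: float(totals["cmp"]["cost"].mean())},
        mean_qalys={ref.name: float(totals["ref"]["qalys"].mean()),
                    cmp_.name: float(totals["cmp"]["qalys"].mean())},
        quadrant_shares=shares,
        wtp_grid=wtp_grid,
        prob_cost_effective=prob,
        warnings=sorted(set(warnings)),
        metadata={
            "shared_utility_coupling": True,
            "timing_fixed": True,
            "varied_parameters": sorted(draws),
        },
    )


def _fast_override(
    params: ComparatorParameterSet, values: Mapping[str, float]
) -> ComparatorParameterSet:
    """Validation-free nested override for hot loops (draws are in-domain
    by construction)."""
    sections: dict[str, dict[str, float]] = {}
    for path, v in values.items():
        sec, fld = path.split(".", 1)
        sections.setdefault(sec, {})[fld] = float(v)
    update = {
        sec: getattr(params, sec).model_copy(update=upd) for sec, upd in sections.items()
    }
    return params.model_copy(update=update)


def ceac(output: PSAOutput, wtp_grid: Sequence[float]) -> np.ndarray:
    """Probability cost-effective (NMB ≥ 0) at each willingness-to-pay."""
    grid = np.asarray(list(wtp_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("empty willingness-to-pay grid")
    return np.array(
        [np.mean(l * output.delta_qalys - output.delta_cost >= 0.0) for l in grid]
    )


# ---------------------------------------------------------------------------
# price threshold


def price_threshold(
    ref: ComparatorParameterSet,
    cmp_: ComparatorParameterSet,
    settings: ModelSettings,
    table: LifeTable,
    target_icer: float,
    price_bounds: tuple[float, float] = (0.0, 200_000.0),
    tol: float = 0.5,
) -> float:
    """Reference-arm device price at which the ICER reaches a target.

    Bisection with full deterministic reruns; the root must lie in the
    trade-off region (positive incremental cost and QALYs), above any
    dominance region.  ``tol`` is on the ICER in AUD/QALY.
    """
    res_c = evaluate(cmp_, settings, table)
    d_qalys = evaluate(ref, settings, table).total_qalys - res_c.total_qalys
    if d_qalys <= 0:
        raise ValueError("price threshold undefined: no incremental QALY gain")

    def gap(price: float) -> float:
        # ICER gap scaled by the (price-independent) QALY gain
        res_r = evaluate(
            apply_overrides(ref, {"costs.device_acquisition": price}), settings, table
        )
        inc = compare(res_r, res_c, settings.wtp_threshold)
        return inc.delta_cost - target_icer * inc.delta_qalys

    lo, hi = price_bounds
    if gap(lo) > 0 or gap(hi) < 0:
        raise ValueError(
            f"target ICER {target_icer} not reachable within price bounds {price_bounds}"
        )
    while True:
        mid = 0.5 * (lo + hi)
        g = gap(mid)
        if abs(g) < tol * d_qalys or hi - lo < 1e-9:
            return mid
        if g > 0:
            hi = mid
        else:
            lo = mid
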