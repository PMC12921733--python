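"""Validated model inputs for one comparator arm and the run settings.

All monetary amounts are Australian dollars (AUD, 2024 tariffs), event
probabilities are per 6-month model cycle unless a different cycle length is
set, and times are years.  Four bundled parameter sets ship with the package
(``sentio``, ``osia``, ``ponto``, ``baha_attract``); user-supplied sets use
the same YAML schema (see ``docs/config_schema.md``).
"""

from __future__ import annotations

import importlib.resources
from typing import Any, Literal, Mapping, Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

__all__ = [
    "TransitionProbabilities",
    "CostSet",
    "SubgroupUtilities",
    "UtilitySet",
    "EventTimingModel",
    "ModelSettings",
    "ComparatorParameterSet",
    "BUNDLED_COMPARATORS",
    "bundled_defaults",
    "default_settings",
    "load_parameters",
    "load_settings",
    "save_parameters",
    "apply_overrides",
]

BUNDLED_COMPARATORS = ("sentio", "osia", "ponto", "baha_attract")


class _Frozen(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")


def _check_unit(name: str, value: float) -> float:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value}")
    return value


class TransitionProbabilities(_Frozen):
    """Per-cycle probabilities of the recurring clinical events.

    ``explantation`` permanently moves patients off the device;
    ``ae_reimplantation`` moves first-implant patients to a second implant
    (at most once per patient); the remaining events do not change health
    state.  Each field carries a standard error for the sensitivity
    machinery.
    """

    explantation: float
    explantation_se: float = Field(ge=0)
    revision: float
    revision_se: float = Field(ge=0)
    ae_reimplantation: float
    ae_reimplantation_se: float = Field(ge=0)
    soft_tissue: float
    soft_tissue_se: float = Field(ge=0)
    pain: float
    pain_se: float = Field(ge=0)

    @field_validator("explantation", "revision", "ae_reimplantation", "soft_tissue", "pain")
    @classmethod
    def _unit_interval(cls, v: float, info) -> float:
        return _check_unit(info.field_name, v)

    @model_validator(mode="after")
    def _competing_exits(self) -> "TransitionProbabilities":
        # explantation and AE-reimplantation both drain the first-implant state
        if self.explantation + self.ae_reimplantation > 1.0:
            raise ValueError(
                "explantation + ae_reimplantation exceed 1 "
                f"({self.explantation} + {self.ae_reimplantation})"
            )
        return self


class CostSet(_Frozen):
    """Unit costs in AUD. Per-cycle items are per 6-month cycle."""

    device_acquisition: float = Field(ge=0)
    sp_replacement_device: float = Field(ge=0)
    surgery_implantation: float = Field(ge=0)
    anaesthesia: float = Field(ge=0)
    anaesthesia_fraction: float
    hospitalisation: float = Field(ge=0)
    post_surgery_audiologist_bundle: float = Field(ge=0)
    post_surgery_specialist: float = Field(ge=0)
    sp_replacement_visit: float = Field(ge=0)
    ae_management_per_event: float = Field(ge=0)
    hcru_per_cycle: float = Field(ge=0)
    battery_per_cycle: float = Field(ge=0)

    @field_validator("anaesthesia_fraction")
    @classmethod
    def _fraction(cls, v: float) -> float:
        return _check_unit("anaesthesia_fraction", v)


class SubgroupUtilities(_Frozen):
    on_bchi: float
    on_bchi_se: float = Field(ge=0)
    off_bchi: float
    off_bchi_se: float = Field(ge=0)
    on_state_decrement: float = Field(le=0, default=0.0)

    @field_validator("on_bchi", "off_bchi")
    @classmethod
    def _unit(cls, v: float, info) -> float:
        return _check_unit(info.field_name, v)


class UtilitySet(_Frozen):
    """Health-state utility weights and per-event disutilities.

    ``on_state_decrement`` is a signed utility decrement applied while on the
    device (nonzero only for the passive transcutaneous system).
    ``soft_tissue_decrement`` is a health-state utility decrement sustained
    for ``soft_tissue_duration_years`` per event; ``pain_decrement`` is
    already a per-event QALY loss (scaled to a three-day episode at source).
    """

    on_bchi: float
    on_bchi_se: float = Field(ge=0)
    off_bchi: float
    off_bchi_se: float = Field(ge=0)
    on_state_decrement: float = Field(le=0, default=0.0)
    soft_tissue_decrement: float = Field(le=0)
    soft_tissue_decrement_se: float = Field(ge=0)
    soft_tissue_duration_years: float = Field(gt=0, default=0.25)
    pain_decrement: float = Field(le=0)
    pain_decrement_se: float = Field(ge=0)
    subgroups: dict[str, SubgroupUtilities] = Field(default_factory=dict)

    @field_validator("on_bchi", "off_bchi")
    @classmethod
    def _unit(cls, v: float, info) -> float:
        return _check_unit(info.field_name, v)

    def for_subgroup(self, subgroup: str) -> tuple[float, float, float]:
        """(u_on, u_off, on-state decrement) for a patient subgroup.

        ``"all"`` returns the base-case fields; other names must be present
        in ``subgroups`` (the bundled sets ship ``chl_mhl`` and ``ssd``).
        """
        if subgroup == "all":
            return self.on_bchi, self.off_bchi, self.on_state_decrement
        try:
            sg = self.subgroups[subgroup]
        except KeyError:
            valid = ["all", *self.subgroups]
            raise KeyError(f"unknown utility subgroup {subgroup!r}; valid: {valid}") from None
        return sg.on_bchi, sg.off_bchi, sg.on_state_decrement


class EventTimingModel(_Frozen):
    """Timing of the recurring device-clock events.

    Anticipated reimplantation and sound-processor (SP) replacement are
    renewal processes on a device-age clock: inter-event times follow the
    chosen family with the stated mean and coefficient of variation (CV).
    """

    anticipated_reimplantation_mean: float = Field(gt=0)
    sp_replacement_mean: float = Field(gt=0)
    coefficient_of_variation: float = 0.35
    anticipated_cv: Optional[float] = None
    sp_cv: Optional[float] = None
    distribution_family: Literal["gamma", "lognormal", "deterministic"] = "gamma"
    compliance_anticipated: float = 1.0
    compliance_sp: float = 1.0
    anticipated_enabled: bool = True

    @field_validator("compliance_anticipated", "compliance_sp")
    @classmethod
    def _fraction(cls, v: float, info) -> float:
        return _check_unit(info.field_name, v)

    @model_validator(mode="after")
    def _cv_positive(self) -> "EventTimingModel":
        if self.distribution_family != "deterministic":
            for cv in (self.coefficient_of_variation, self.anticipated_cv, self.sp_cv):
                if cv is not None and cv <= 0:
                    raise ValueError("coefficient of variation must be > 0")
        return self

    def cv_for(self, which: str) -> float:
        if which == "anticipated_reimplantation":
            return self.anticipated_cv if self.anticipated_cv is not None else self.coefficient_of_variation
        if which == "sp_replacement":
            return self.sp_cv if self.sp_cv is not None else self.coefficient_of_variation
        raise ValueError(f"unknown timed event {which!r}")


class ModelSettings(_Frozen):
    """Run settings shared by both arms of a comparison.

    ``horizon`` is in years or the string ``"lifetime"`` (run until the
    cohort is extinct or the life table's terminal age is reached).
    ``discount_compounding`` chooses between annual-step discounting (factor
    updated at whole-year boundaries, the spreadsheet convention, default)
    and continuous per-cycle compounding. ``event_discount_timing`` places
    event costs at the start, midpoint or end of their cycle.
    """

    cycle_length: float = Field(gt=0, default=0.5)
    horizon: Union[float, Literal["lifetime"]] = 15.0
    discount_rate_costs: float = Field(ge=0, default=0.05)
    discount_rate_qalys: float = Field(ge=0, default=0.05)
    start_age: float = Field(ge=0, default=40.0)
    sex_mix: float = 0.5  # proportion female
    half_cycle_correction: bool = True
    wtp_threshold: float = Field(ge=0, default=50_000.0)
    discount_compounding: Literal["annual", "cycle"] = "annual"
    event_discount_timing: Literal["start", "midpoint", "end"] = "start"
    utility_subgroup: str = "all"

    @field_validator("sex_mix")
    @classmethod
    def _mix(cls, v: float) -> float:
        return _check_unit("sex_mix", v)

    @model_validator(mode="after")
    def _horizon_ok(self) -> "ModelSettings":
        if self.horizon != "lifetime" and float(self.horizon) < self.cycle_length:
            raise ValueError("horizon must cover at least one cycle")
        return self


class ComparatorParameterSet(_Frozen):
    """All inputs for one device arm: probabilities, costs, utilities, timing."""

    name: str
    transitions: TransitionProbabilities
    costs: CostSet
    utilities: UtilitySet
    timing: EventTimingModel

    def to_config(self) -> dict[str, Any]:
        return self.model_dump(mode="json")


# ---------------------------------------------------------------------------
# config I/O


def _read_source(source: Any) -> dict[str, Any]:
    if isinstance(source, Mapping):
        return dict(source)
    with open(source, "r") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"config {source} did not parse to a mapping")
    return data


def load_parameters(source: Any) -> ComparatorParameterSet:
    """Load and validate a comparator parameter set from YAML or a mapping.

    Raises ``ValueError`` naming the offending field on a missing field,
    out-of-range probability/utility or negative cost.
    """
    return ComparatorParameterSet.model_validate(_read_source(source))


def load_settings(source: Any) -> ModelSettings:
    return ModelSettings.model_validate(_read_source(source))


def save_parameters(params: ComparatorParameterSet, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_config(), fh, sort_keys=False)


def _data_dir():
    return importlib.resources.files("bchicea") / "data" / "configs"


def bundled_defaults(comparator: str) -> ComparatorParameterSet:
    """Return the packaged base-case parameter set for a named comparator."""
    name = comparator.lower()
    if name not in BUNDLED_COMPARATORS:
        raise KeyError(
            f"unknown comparator {comparator!r}; valid names: {list(BUNDLED_COMPARATORS)}"
        )
    with importlib.resources.as_file(_data_dir() / f"{name}.yaml") as p:
        return load_parameters(p)


def default_settings() -> ModelSettings:
    """The packaged base-case settings (6-month cycles, 15 y, 5%, age 40)."""
    with importlib.resources.as_file(_data_dir() / "settings.yaml") as p:
        return load_settings(p)


# ---------------------------------------------------------------------------
# overrides


def _set_path(data: dict[str, Any], path: str, value: Any) -> None:
    parts = path.split(".")
    node = data
    for key in parts[:-1]:
        if not isinstance(node, dict) or key not in node:
            raise KeyError(f"unknown parameter path {path!r}")
        node = node[key]
    if not isinstance(node, dict) or parts[-1] not in node:
        raise KeyError(f"unknown parameter path {path!r}")
    node[parts[-1]] = value


def apply_overrides(
    base: ComparatorParameterSet, overrides: Mapping[str, Any]
) -> ComparatorParameterSet:
    """Return a new validated set with dotted-path overrides applied.

    ``base`` is left unmodified.  Example path: ``"costs.device_acquisition"``.
    """
    data = base.model_dump()
    for path, value in overrides.items():
        _set_path(data, path, value)
    return ComparatorParameterSet.model_validate(data)


def apply_settings_overrides(
    base: ModelSettings, overrides: Mapping[str, Any]
) -> ModelSettings:
    """Same as :func:`apply_overrides` but for run settings (flat paths)."""
    data = base.model_dump()
    for path, value in overrides.items():
        if path not in data:
            raise KeyError(f"unknown settings field {path!r}")
        data[path] = value
    return ModelSettings.model_validate(data)
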