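"""Mortality inputs and synthetic test data.

The cohort model needs age- and sex-specific annual death probabilities
(q_annual).  A bundled Australian-style table ships with the package (a
synthetic Gompertz–Makeham table calibrated to published Australian adult
mortality summaries — see the fixture header); user-supplied tables in the
same three-column TSV format (age, sex, q_annual) are accepted anywhere a
life table is taken.

This module is also the synthetic-data generator for the test suite:
parametric Gompertz–Makeham life tables and random valid comparator
parameter sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import (
    ComparatorParameterSet,
    CostSet,
    EventTimingModel,
    TransitionProbabilities,
    UtilitySet,
)

__all__ = [
    "LifeTable",
    "GompertzMakehamParams",
    "bundled_life_table",
    "synthetic_life_table",
    "cycle_mortality",
    "synthetic_parameter_set",
]

SEXES = ("female", "male")


class LifeTable:
    """Age × sex annual death probabilities, ages 0..terminal (absorbing).

    Wraps a tidy DataFrame with columns ``age``, ``sex``, ``q_annual``.
    Ages must be contiguous from 0 to a terminal age at which q_annual = 1
    for both sexes.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"age", "sex", "q_annual"}
        if not required.issubset(frame.columns):
            raise ValueError(f"life table needs columns {sorted(required)}")
        frame = frame[["age", "sex", "q_annual"]].copy()
        frame["age"] = frame["age"].astype(int)
        self._q: dict[str, np.ndarray] = {}
        terminal = None
        for sex in SEXES:
            sub = frame[frame["sex"] == sex].sort_values("age")
            if sub.empty:
                raise ValueError(f"life table is missing sex {sex!r}")
            ages = sub["age"].to_numpy()
            if ages[0] != 0 or not np.array_equal(ages, np.arange(len(ages))):
                raise ValueError(f"ages for {sex!r} must be contiguous from 0")
            q = sub["q_annual"].to_numpy(dtype=float)
            if np.any((q < 0) | (q > 1)):
                raise ValueError("q_annual outside [0, 1]")
            if q[-1] != 1.0:
                raise ValueError("q_annual must be 1 at the terminal age")
            if terminal is None:
                terminal = ages[-1]
            elif ages[-1] != terminal:
                raise ValueError("sexes cover different age ranges")
            self._q[sex] = q
        self.terminal_age = int(terminal)
        self.frame = frame.sort_values(["sex", "age"]).reset_index(drop=True)

    def q_annual(self, age: float, sex: str) -> float:
        """Annual death probability at the integer age containing ``age``."""
        idx = min(int(np.floor(age)), self.terminal_age)
        return float(self._q[sex][idx])

    def mixed_annual(self, sex_mix: float) -> np.ndarray:
        """Sex-mix-weighted annual q by integer age (mix = proportion female)."""
        return sex_mix * self._q["female"] + (1.0 - sex_mix) * self._q["male"]

    @classmethod
    def from_tsv(cls, path) -> "LifeTable":
        frame = pd.read_csv(path, sep="\t", comment="#")
        return cls(frame)

    def to_tsv(self, path, header: str | None = None) -> None:
        with open(path, "w") as fh:
            if header:
                for line in header.rstrip().splitlines():
                    fh.write(f"# {line}\n")
            self.frame.to_csv(fh, sep="\t", index=False, float_format="%.6g")


@dataclass(frozen=True)
class GompertzMakehamParams:
    """Hazard h(x) = makeham + gompertz_scale * exp(gompertz_shape * x)."""

    makeham: float
    gompertz_scale: float
    gompertz_shape: float

    def __post_init__(self):
        if self.makeham < 0 or self.gompertz_scale < 0:
            raise ValueError("hazard components must be non-negative")
        if self.gompertz_shape <= 0:
            raise ValueError("gompertz_shape must be > 0")


def synthetic_life_table(
    params_female: GompertzMakehamParams,
    params_male: GompertzMakehamParams | None = None,
    terminal_age: int = 100,
) -> LifeTable:
    """Parametric life table: q(age) = 1 − exp(−∫ hazard over one year)."""
    if terminal_age < 1:
        raise ValueError("terminal_age must be at least 1")
    if params_male is None:
        params_male = params_female
    ages = np.arange(terminal_age + 1, dtype=float)
    rows = []
    for sex, p in (("female", params_female), ("male", params_male)):
        c = p.gompertz_shape
        cum_hazard = p.makeham + p.gompertz_scale / c * (np.exp(c * (ages + 1)) - np.exp(c * ages))
        q = np.clip(1.0 - np.exp(-cum_hazard), 0.0, 1.0)
        q[-1] = 1.0
        rows.append(pd.DataFrame({"age": ages.astype(int), "sex": sex, "q_annual": q}))
    return LifeTable(pd.concat(rows, ignore_index=True))


# Calibrated to ABS-style Australian adult mortality (q40 ≈ 0.76/1.34 per
# 1000 for females/males); used to generate the bundled fixture.
AUSTRALIA_SYNTHETIC_FEMALE = GompertzMakehamParams(2.0e-4, 1.25e-5, 0.095)
AUSTRALIA_SYNTHETIC_MALE = GompertzMakehamParams(3.0e-4, 2.33e-5, 0.095)


def bundled_life_table() -> LifeTable:
    """The packaged Australian-style life table (synthetic, see file header)."""
    import importlib.resources

    path = importlib.resources.files("bchicea") / "data" / "australia_synthetic_life_table.tsv"
    with importlib.resources.as_file(path) as p:
        return LifeTable.from_tsv(p)


def cycle_mortality(table: LifeTable, age: float, sex_mix: float, cycle_length: float) -> float:
    """Per-cycle death probability at a model age.

    Uses the constant-hazard-within-year conversion
    p = 1 − (1 − q_mix)^cycle_length, with q_mix the sex-mix-weighted annual
    probability at floor(age).  Ages beyond the table use the terminal
    (absorbing) row.
    """
    idx = min(int(np.floor(age)), table.terminal_age)
    q_mix = sex_mix * table.q_annual(idx, "female") + (1.0 - sex_mix) * table.q_annual(idx, "male")
    return 1.0 - (1.0 - q_mix) ** cycle_length


def synthetic_parameter_set(seed: int) -> ComparatorParameterSet:
    """Reproducible random parameter set satisfying every type invariant.

    Probabilities are drawn in [0, 0.1] (well inside the competing-exit
    bound), costs in plausible AUD ranges, utilities in [0.5, 1].  Used by
    the property tests and the microsimulation oracle.
    """
    rng = np.random.default_rng(seed)

    def p() -> float:
        return float(rng.uniform(0.0, 0.1))

    probs = {k: p() for k in ("explantation", "revision", "ae_reimplantation", "soft_tissue", "pain")}
    transitions = TransitionProbabilities(
        **probs, **{f"{k}_se": float(rng.uniform(0, 0.02)) for k in probs}
    )
    costs = CostSet(
        device_acquisition=float(rng.uniform(5_000, 20_000)),
        sp_replacement_device=float(rng.uniform(3_000, 8_000)),
        surgery_implantation=float(rng.uniform(300, 1_500)),
        anaesthesia=float(rng.uniform(100, 500)),
        anaesthesia_fraction=float(rng.uniform(0, 1)),
        hospitalisation=float(rng.uniform(2_000, 8_000)),
        post_surgery_audiologist_bundle=float(rng.uniform(100, 600)),
        post_surgery_specialist=float(rng.uniform(30, 100)),
        sp_replacement_visit=float(rng.uniform(80, 300)),
        ae_management_per_event=float(rng.uniform(50, 400)),
        hcru_per_cycle=float(rng.uniform(40, 200)),
        battery_per_cycle=float(rng.uniform(3, 40)),
    )
    u_on = float(rng.uniform(0.6, 1.0))
    u_off = float(rng.uniform(0.5, u_on))
    utilities = UtilitySet(
        on_bchi=u_on,
        on_bchi_se=float(rng.uniform(0.01, 0.05)),
        off_bchi=u_off,
        off_bchi_se=float(rng.uniform(0.01, 0.05)),
        on_state_decrement=-float(rng.uniform(0, 0.05)),
        soft_tissue_decrement=-float(rng.uniform(0.01, 0.06)),
        soft_tissue_decrement_se=float(rng.uniform(0.001, 0.01)),
        soft_tissue_duration_years=0.25,
        pain_decrement=-float(rng.uniform(0.001, 0.005)),
        pain_decrement_se=float(rng.uniform(0.0005, 0.002)),
    )
    timing = EventTimingModel(
        anticipated_reimplantation_mean=float(rng.uniform(6, 20)),
        sp_replacement_mean=float(rng.uniform(3, 8)),
        coefficient_of_variation=float(rng.uniform(0.2, 0.6)),
        compliance_anticipated=float(rng.uniform(0.7, 1.0)),
        compliance_sp=float(rng.uniform(0.7, 1.0)),
        anticipated_enabled=True,
    )
    return ComparatorParameterSet(
        name=f"synthetic-{seed}",
        transitions=transitions,
        costs=costs,
        utilities=utilities,
        timing=timing,
    )
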