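"""Report writers and the run manifest.

Every command writes a manifest (inputs, seed, parameter fingerprints,
software version) next to its outputs so a run can be reproduced from the
output directory alone.  Tables are plain text (TSV for machine reading,
aligned text for humans); currency and units are echoed in every header.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .economics import COST_CATEGORIES, EconomicResult, IncrementalResult
from .engine import CohortTrace
from .parameters import ComparatorParameterSet, ModelSettings
from .uncertainty import PSAOutput, ScenarioResult, TornadoEntry

__all__ = [
    "RunManifest",
    "write_manifest",
    "results_table",
    "write_results",
    "write_trace",
    "write_tornado",
    "write_scenarios",
    "write_psa",
]

_HEADER = "# currency: AUD (2024 tariffs); QALYs and life years discounted per settings\n"


@dataclass
class RunManifest:
    command: str
    seed: int | None
    config_fingerprints: dict[str, str]
    version: str = __version__
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat(timespec="seconds")
    )

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2) + "\n")


def _fingerprint(obj) -> str:
    if hasattr(obj, "model_dump"):
        payload = json.dumps(obj.model_dump(mode="json"), sort_keys=True)
    else:
        payload = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_manifest(
    out_dir: Path,
    command: str,
    *,
    seed: int | None = None,
    params: Sequence[ComparatorParameterSet] = (),
    settings: ModelSettings | None = None,
    extra: dict | None = None,
) -> RunManifest:
    prints = {p.name: _fingerprint(p) for p in params}
    if settings is not None:
        prints["settings"] = _fingerprint(settings)
    if extra:
        prints.update({k: _fingerprint(v) for k, v in extra.items()})
    manifest = RunManifest(command=command, seed=seed, config_fingerprints=prints)
    manifest.write(out_dir / "manifest.json")
    return manifest


def results_table(
    reference: EconomicResult, comparator: EconomicResult, inc: IncrementalResult
) -> pd.DataFrame:
    """Deterministic results in the disaggregated-cost table shape."""
    rows = []
    for cat in COST_CATEGORIES:
        rows.append(
            (f"cost_{cat}", reference.costs[cat], comparator.costs[cat],
             reference.costs[cat] - comparator.costs[cat])
        )
    rows.append(("total_cost", reference.total_cost, comparator.total_cost, inc.delta_cost))
    rows.append(("total_qalys", reference.total_qalys, comparator.total_qalys, inc.delta_qalys))
    rows.append(
        ("total_life_years", reference.total_life_years, comparator.total_life_years,
         inc.delta_life_years)
    )
    return pd.DataFrame(
        rows, columns=["quantity", reference.name, comparator.name, "difference"]
    )


def write_results(
    out_dir: Path,
    reference: EconomicResult,
    comparator: EconomicResult,
    inc: IncrementalResult,
) -> pd.DataFrame:
    table = results_table(reference, comparator, inc)
    with open(out_dir / "results.tsv", "w") as fh:
        fh.write(_HEADER)
        table.to_csv(fh, sep="\t", index=False, float_format="%.6f")
    icer = "dominating" if inc.classification.value == "dominant" else (
        f"{inc.icer:.0f}" if inc.icer is not None else inc.classification.value
    )
    summary = {
        "reference": reference.name,
        "comparator": comparator.name,
        "delta_cost_aud": inc.delta_cost,
        "delta_qalys": inc.delta_qalys,
        "delta_life_years": inc.delta_life_years,
        "classification": inc.classification.value,
        "icer_aud_per_qaly": inc.icer,
        "icer_display": icer,
        "nmb_aud": inc.nmb,
        "wtp_aud_per_qaly": inc.wtp,
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return table


def write_trace(out_dir: Path, trace: CohortTrace, name: str) -> None:
    with open(out_dir / f"trace_{name}.tsv", "w") as fh:
        fh.write("# cohort trace: occupancies at end of cycle, expected events per cycle\n")
        trace.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.8g")


def write_tornado(out_dir: Path, entries: Sequence[TornadoEntry]) -> None:
    frame = pd.DataFrame(
        [
            (e.parameter, e.low_input, e.high_input, e.nmb_low, e.nmb_high, e.range)
            for e in entries
        ],
        columns=["parameter", "low_input", "high_input", "nmb_low_aud", "nmb_high_aud",
                 "nmb_range_aud"],
    )
    with open(out_dir / "tornado.tsv", "w") as fh:
        fh.write(_HEADER + "# incremental net monetary benefit at 95% CI bounds, ranked\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.4f")


def write_scenarios(out_dir: Path, results: Sequence[ScenarioResult]) -> None:
    frame = pd.DataFrame(
        [
            (
                r.name,
                r.incremental.delta_cost,
                r.incremental.delta_qalys,
                r.pct_change_cost,
                r.pct_change_qalys,
                r.incremental.classification.value,
                r.incremental.icer if r.incremental.icer is not None else "",
            )
            for r in results
        ],
        columns=["scenario", "delta_cost_aud", "delta_qalys", "pct_change_cost",
                 "pct_change_qalys", "classification", "icer_aud_per_qaly"],
    )
    with open(out_dir / "scenarios.tsv", "w") as fh:
        fh.write(_HEADER + "# signed deltas and percent changes vs the base case\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.4f")


def write_psa(out_dir: Path, output: PSAOutput) -> None:
    with open(out_dir / "ce_plane.tsv", "w") as fh:
        fh.write(_HEADER + "# one row per PSA iteration: reference minus comparator\n")
        pd.DataFrame(
            {"delta_qalys": output.delta_qalys, "delta_cost_aud": output.delta_cost}
        ).to_csv(fh, sep="\t", index=False, float_format="%.6f")
    with open(out_dir / "ceac.tsv", "w") as fh:
        fh.write("# probability cost-effective by willingness to pay (AUD/QALY)\n")
        pd.DataFrame(
            {"wtp_aud_per_qaly": output.wtp_grid,
             "prob_cost_effective": output.prob_cost_effective}
        ).to_csv(fh, sep="\t", index=False, float_format="%.6f")
    summary = {
        "seed": output.seed,
        "n_iterations": output.n_iterations,
        "mean_cost_aud": output.mean_cost,
        "mean_qalys": output.mean_qalys,
        "quadrant_shares": output.quadrant_shares,
        "prob_cost_effective_at_50000": output.probability_cost_effective(50_000.0),
        "metadata": output.metadata,
        "warnings": output.warnings,  # surfaced in the report footer
    }
    (out_dir / "psa_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
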