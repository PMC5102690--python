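"""CSV export of the model's result tables and figure data.

Exports mirror the shapes of the published summary tables: the panel cost
decomposition, the frame-by-frame BIA with budget impacts, the institutional
case-study summary, the cost-versus-throughput curve and the tornado series.
Euro cells are plain integers (half-away-from-zero) so files stay machine
readable; unrounded exports are available via ``rounding="none"``.

A manifest (inputs, package version, seed) is written next to the tables;
it contains nothing time-dependent, so a fixed config + seed yields
byte-identical artifacts across runs.
"""

from __future__ import annotations

import json
from dataclasses import replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import __version__
from .abc_costing import PanelCostSpec, RunPlan, cost_curve, cost_per_sample
from .bia import BiaInputs, INDICATIONS, TIMEFRAMES
from .case_study import PeriodSummary
from .rounding import round_half_away
from .sensitivity import TornadoEntry

BASE_PLAN = RunPlan(samples_per_run=24, runs_per_week=1.0, fill_fraction=0.85)


def _euro(x: float, rounding: str) -> float | int:
    return round_half_away(x) if rounding == "whole_euro" else x


def panel_cost_table(
    specs: Iterable[PanelCostSpec],
    plan: RunPlan = BASE_PLAN,
    rounding: str = "whole_euro",
) -> pd.DataFrame:
    """Cost decomposition plus per-sample total under ``plan`` for each panel."""
    rows = []
    for spec in specs:
        capped_plan = plan
        if plan.samples_per_run > spec.max_samples_per_run:
            capped_plan = replace(plan, samples_per_run=spec.max_samples_per_run)
        breakdown = cost_per_sample(spec, capped_plan)
        rows.append(
            {
                "panel": spec.panel,
                "platform": spec.platform,
                "fixed_yearly_eur": _euro(spec.fixed_yearly, rounding),
                "fixed_per_run_personnel_eur": _euro(spec.fixed_per_run_personnel, rounding),
                "fixed_per_run_material_eur": _euro(spec.fixed_per_run_material, rounding),
                "variable_per_sample_personnel_eur": _euro(spec.variable_per_sample_personnel, rounding),
                "variable_per_sample_material_eur": _euro(spec.variable_per_sample_material, rounding),
                "samples_per_run": capped_plan.samples_per_run,
                "cost_per_sample_eur": _euro(breakdown.cost_per_patient_sample, rounding),
            }
        )
    return pd.DataFrame(rows)


def bia_table(inputs: BiaInputs, rounding: str = "whole_euro") -> pd.DataFrame:
    """Per-patient and population cost per frame plus frame-to-frame impacts."""
    rows = []
    for timeframe in TIMEFRAMES:
        for indication in INDICATIONS:
            rows.append(
                {
                    "row": "cost",
                    "timeframe": timeframe,
                    "indication": indication,
                    "per_patient_eur": _euro(
                        inputs.cost_per_patient(timeframe, indication), rounding
                    ),
                    "population_eur": _euro(
                        inputs.population_cost(timeframe, indication), rounding
                    ),
                }
            )
    for from_tf, to_tf in zip(TIMEFRAMES[:-1], TIMEFRAMES[1:]):
        for indication in INDICATIONS:
            impact = inputs.budget_impact(from_tf, to_tf, indication)
            rows.append(
                {
                    "row": f"impact:{from_tf}->{to_tf}",
                    "timeframe": to_tf,
                    "indication": indication,
                    "per_patient_eur": _euro(impact.per_patient_delta, rounding),
                    "population_eur": _euro(impact.population_delta, rounding),
                }
            )
    return pd.DataFrame(rows)


def case_study_table(
    summaries: Sequence[PeriodSummary],
    yearly_patients: dict[str, int],
    rounding: str = "whole_euro",
) -> pd.DataFrame:
    """Period summaries annualised to the institutional population."""
    rows = []
    for s in summaries:
        yearly = yearly_patients[s.indication]
        rows.append(
            {
                "indication": s.indication,
                "period": s.period,
                "n_patients": s.n_patients,
                "mean_tests": s.tests_per_patient.mean,
                "per_patient_eur": _euro(s.cost_per_patient.mean, rounding),
                "yearly_patients": yearly,
                "population_eur": _euro(
                    yearly * s.cost_per_patient.mean, rounding
                ),
            }
        )
    return pd.DataFrame(rows)


def curve_table(
    spec: PanelCostSpec,
    plan_template: RunPlan = BASE_PLAN,
    sample_counts: Sequence[int] | None = None,
    rounding: str = "whole_euro",
) -> pd.DataFrame:
    """The cost-versus-samples-per-run series (full runs)."""
    if sample_counts is None:
        sample_counts = list(range(4, spec.max_samples_per_run + 1))
    points = cost_curve(spec, plan_template, sample_counts)
    return pd.DataFrame(
        [
            {"samples_per_run": n, "cost_per_sample_eur": _euro(c, rounding)}
            for n, c in points
        ]
    )


def tornado_table(
    entries: Sequence[TornadoEntry], rounding: str = "whole_euro"
) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "param": e.name,
                "low_outcome_eur": _euro(e.outcome_at_low, rounding),
                "high_outcome_eur": _euro(e.outcome_at_high, rounding),
                "width_eur": _euro(e.width, rounding),
            }
            for e in entries
        ]
    )


def write_tables(
    tables: dict[str, pd.DataFrame],
    out_dir: str | Path,
    manifest: dict | None = None,
) -> list[Path]:
    """Write each table as ``<name>.csv`` plus a run manifest.

    Deterministic: no timestamps; identical inputs give identical bytes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, frame in tables.items():
        path = out / f"{name}.csv"
        frame.to_csv(path, index=False)
        written.append(path)
    manifest_payload = {
        "package": "panelcost",
        "version": __version__,
        "tables": sorted(tables),
        **(manifest or {}),
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest_payload, indent=2, sort_keys=True) + "\n")
    written.append(manifest_path)
    return written
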