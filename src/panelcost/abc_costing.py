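"""Activity-based costing (ABC) for targeted NGS gene panels.

The cost of running a diagnostic sequencing panel is decomposed into

* fixed yearly costs (equipment annualisation, spread uniformly over runs),
* fixed costs per run (personnel time and consumables that do not depend on
  how many samples are booked), and
* variable costs per sample (per-sample personnel time and consumables).

Cost per *patient* sample then depends on the run plan: how many samples are
booked per run, how many runs are executed per week, and how full the run is
on average.  Control (quality-assurance) samples incur variable cost only and
their cost is absorbed by the patient samples of the run.  A configurable
overhead fraction (default 30%) is applied multiplicatively on top.

Two panels are modelled: a small amplicon panel (~48 genes) and a medium
capture panel (~178 genes, DNA part only), each runnable on a benchtop
(Miseq-class) or high-throughput (Hiseq-class) sequencer.  The medium panel
on the benchtop machine is capacity-limited to four samples per run by
coverage-depth requirements; every other combination takes up to 48.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .errors import CapacityError, ConfigurationError, ValidationError
from .rounding import round_half_away

PERSONNEL_ROLES = (
    "secretary",
    "technician",
    "pathologist",
    "molecular_biologist",
    "bioinformatician",
    "board_member",
)

PANELS = ("small_tgp", "medium_tgp")
PLATFORMS = ("miseq", "hiseq")


@dataclass(frozen=True)
class ActivityStep:
    """One process activity consuming personnel time, materials or equipment.

    Time and material can be booked per sample (variable) or per run (fixed);
    equipment enters as an annualised yearly cost.
    """

    label: str
    role: str = "technician"
    minutes_per_sample: float = 0.0
    minutes_per_run: float = 0.0
    material_cost_per_sample: float = 0.0
    material_cost_per_run: float = 0.0
    equipment_annual_cost: float = 0.0

    def __post_init__(self) -> None:
        fields = (
            self.minutes_per_sample,
            self.minutes_per_run,
            self.material_cost_per_sample,
            self.material_cost_per_run,
            self.equipment_annual_cost,
        )
        if any(v < 0 for v in fields):
            raise ValidationError(
                f"activity step {self.label!r}: negative time or cost"
            )
        if all(v == 0 for v in fields):
            raise ValidationError(
                f"activity step {self.label!r} contributes to no cost field"
            )


@dataclass(frozen=True)
class PersonnelRate:
    """Cost per direct productive minute for one personnel category."""

    role: str
    euros_per_minute: float

    def __post_init__(self) -> None:
        if self.euros_per_minute <= 0:
            raise ValidationError(
                f"rate for role {self.role!r} must be positive"
            )


@dataclass(frozen=True)
class PanelCostSpec:
    """Cost decomposition of one panel on one platform (the Table-1 object)."""

    panel: str
    platform: str
    fixed_yearly: float
    fixed_per_run_personnel: float
    fixed_per_run_material: float
    variable_per_sample_personnel: float
    variable_per_sample_material: float
    max_samples_per_run: int

    def __post_init__(self) -> None:
        monetary = (
            self.fixed_yearly,
            self.fixed_per_run_personnel,
            self.fixed_per_run_material,
            self.variable_per_sample_personnel,
            self.variable_per_sample_material,
        )
        if any(v < 0 for v in monetary):
            raise ValidationError("panel cost components must be non-negative")
        if self.panel in PANELS and self.platform in PLATFORMS:
            expected = 4 if (self.panel, self.platform) == ("medium_tgp", "miseq") else 48
            if self.max_samples_per_run != expected:
                raise ValidationError(
                    f"{self.panel} on {self.platform} holds "
                    f"{expected} samples per run, got {self.max_samples_per_run}"
                )
        elif self.max_samples_per_run < 1:
            raise ValidationError("max_samples_per_run must be positive")

    @property
    def fixed_per_run(self) -> float:
        return self.fixed_per_run_personnel + self.fixed_per_run_material

    @property
    def variable_per_sample(self) -> float:
        return self.variable_per_sample_personnel + self.variable_per_sample_material

    def scaled(self, factor: float) -> "PanelCostSpec":
        """Scale every monetary field by ``factor`` (homogeneity helper)."""
        return replace(
            self,
            fixed_yearly=self.fixed_yearly * factor,
            fixed_per_run_personnel=self.fixed_per_run_personnel * factor,
            fixed_per_run_material=self.fixed_per_run_material * factor,
            variable_per_sample_personnel=self.variable_per_sample_personnel * factor,
            variable_per_sample_material=self.variable_per_sample_material * factor,
        )


@dataclass(frozen=True)
class RunPlan:
    """Throughput assumptions for a sequencing run schedule."""

    samples_per_run: int
    runs_per_week: float = 1.0
    fill_fraction: float = 1.0
    weeks_per_year: int = 52
    overhead_fraction: float = 0.30

    def __post_init__(self) -> None:
        if self.samples_per_run < 1:
            raise ValidationError("samples_per_run must be a positive integer")
        if self.runs_per_week <= 0:
            raise ValidationError("runs_per_week must be positive")
        if not 0 < self.fill_fraction <= 1:
            raise ValidationError("fill_fraction must lie in (0, 1]")
        if self.weeks_per_year < 1:
            raise ValidationError("weeks_per_year must be positive")
        if self.overhead_fraction < 0:
            raise ValidationError("overhead_fraction must be non-negative")


@dataclass(frozen=True)
class CostBreakdown:
    """Cost per patient sample split into fixed, variable and overhead shares."""

    cost_per_patient_sample: float
    fixed_share: float
    variable_share: float
    overhead_share: float
    n_patient_samples_effective: float
    n_controls: int

    @property
    def rounded(self) -> int:
        """Whole-euro cost as reported (half away from zero)."""
        return round_half_away(self.cost_per_patient_sample)


def n_controls(patient_samples: int) -> int:
    """Control samples included in a run: one up to 8 booked samples, two from 9."""
    if patient_samples < 1:
        raise ValidationError("a run must book at least one patient sample")
    return 1 if patient_samples <= 8 else 2


def aggregate_panel_costs(
    steps: Iterable[ActivityStep],
    rates: Iterable[PersonnelRate],
    *,
    panel: str = "small_tgp",
    platform: str = "miseq",
    max_samples_per_run: int = 48,
) -> PanelCostSpec:
    """Sum an activity schedule into a :class:`PanelCostSpec`.

    Personnel minutes are priced with the per-role rates; materials and
    equipment are summed directly.  Values are unrounded euros.
    """
    rate_by_role = {r.role: r.euros_per_minute for r in rates}
    fixed_yearly = 0.0
    run_personnel = 0.0
    run_material = 0.0
    var_personnel = 0.0
    var_material = 0.0
    for step in steps:
        if (step.minutes_per_sample or step.minutes_per_run) and step.role not in rate_by_role:
            raise ConfigurationError(
                f"no personnel rate configured for role {step.role!r} "
                f"(step {step.label!r})"
            )
        rate = rate_by_role.get(step.role, 0.0)
        run_personnel += step.minutes_per_run * rate
        var_personnel += step.minutes_per_sample * rate
        run_material += step.material_cost_per_run
        var_material += step.material_cost_per_sample
        fixed_yearly += step.equipment_annual_cost
    return PanelCostSpec(
        panel=panel,
        platform=platform,
        fixed_yearly=fixed_yearly,
        fixed_per_run_personnel=run_personnel,
        fixed_per_run_material=run_material,
        variable_per_sample_personnel=var_personnel,
        variable_per_sample_material=var_material,
        max_samples_per_run=max_samples_per_run,
    )


def cost_per_sample(
    spec: PanelCostSpec,
    plan: RunPlan,
    *,
    controls: int | None = None,
) -> CostBreakdown:
    """Mean cost per patient sample under a run plan.

    The effective number of patient samples is ``fill_fraction ×
    samples_per_run``; the control count keys off the *booked* run size
    (override with ``controls`` for what-if analyses).  Fixed yearly costs are
    spread uniformly over ``weeks_per_year × runs_per_week`` runs.
    """
    if plan.samples_per_run > spec.max_samples_per_run:
        raise CapacityError(
            f"{plan.samples_per_run} samples booked but {spec.panel} on "
            f"{spec.platform} takes at most {spec.max_samples_per_run} per run"
        )
    c = n_controls(plan.samples_per_run) if controls is None else controls
    if c < 0:
        raise ValidationError("control count must be non-negative")
    n_p = plan.fill_fraction * plan.samples_per_run
    runs_per_year = plan.weeks_per_year * plan.runs_per_week
    fixed_share = (spec.fixed_yearly / runs_per_year + spec.fixed_per_run) / n_p
    variable_share = (n_p + c) * spec.variable_per_sample / n_p
    overhead_share = plan.overhead_fraction * (fixed_share + variable_share)
    return CostBreakdown(
        cost_per_patient_sample=fixed_share + variable_share + overhead_share,
        fixed_share=fixed_share,
        variable_share=variable_share,
        overhead_share=overhead_share,
        n_patient_samples_effective=n_p,
        n_controls=c,
    )


def cost_curve(
    spec: PanelCostSpec,
    plan_template: RunPlan,
    sample_counts: Sequence[int],
) -> list[tuple[int, float]]:
    """Cost per sample as a function of booked samples, for completely full runs.

    Mirrors the cost-versus-throughput curve: one run per week (or whatever
    the template says), fill fraction forced to 1.
    """
    points: list[tuple[int, float]] = []
    for count in sample_counts:
        plan = replace(plan_template, samples_per_run=count, fill_fraction=1.0)
        points.append((count, cost_per_sample(spec, plan).cost_per_patient_sample))
    return points
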