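"""Institutional before/after comparison of molecular test utilisation.

Patient-level records (tests requested, mutations observed, treatment-
category flags) from a window before and a window after NGS entered routine
diagnostics are summarised per period, compared variable by variable, and
annualised to an institutional budget impact.

Test selection follows the conventional rule for two-group comparisons:
an independent two-sample t-test for continuous variables that look normal
in both groups (Shapiro–Wilk at α = 0.05), a two-sided Mann–Whitney U-test
otherwise, and Fisher's exact test (two-sided, point-probability method)
for binary variables.  No multiple-testing correction is applied across
variables.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .bia import BudgetImpact, TestCatalog
from .errors import ValidationError
from .rounding import round_half_away

PERIODS = ("before", "after")

#: Continuous per-patient variables compared between periods.
CONTINUOUS_VARIABLES = (
    "tests_per_patient",
    "cost_per_patient",
    "cost_per_test",
    "mutations_per_patient",
)


@dataclass(frozen=True)
class PatientRecord:
    """One patient: the molecular tests requested and what came of them."""

    indication: str
    period: str
    tests: tuple[str, ...]
    mutation_count: int
    category_flags: Mapping[str, bool]
    patient_id: str = ""

    def __post_init__(self) -> None:
        if not self.tests:
            raise ValidationError(
                "a patient record must carry at least one test "
                "(patients enter the cohort because diagnostics were requested)"
            )
        if self.mutation_count < 0:
            raise ValidationError("mutation_count must be non-negative")


@dataclass(frozen=True)
class SummaryStat:
    """Mean with observed range."""

    mean: float
    min: float
    max: float

    def __post_init__(self) -> None:
        if not self.min <= self.mean <= self.max:
            raise ValidationError("require min <= mean <= max")


@dataclass(frozen=True)
class PeriodSummary:
    """Aggregates of one indication × period cohort."""

    indication: str
    period: str
    n_patients: int
    tests_per_patient: SummaryStat
    cost_per_patient: SummaryStat
    cost_per_test: SummaryStat
    mutations_per_patient: SummaryStat
    category_counts: Mapping[str, tuple[int, float]]


@dataclass(frozen=True)
class VariableComparison:
    """Outcome of one between-period test."""

    variable: str
    kind: str  # "continuous" | "binary"
    test: str  # "t" | "mann_whitney" | "fisher"
    p_value: float | None
    significant: bool | None
    degenerate: bool = False


@dataclass(frozen=True)
class ComparisonResult:
    comparisons: Mapping[str, VariableComparison]
    alpha: float = 0.05

    def __getitem__(self, variable: str) -> VariableComparison:
        return self.comparisons[variable]


def summarize_period(
    records: Sequence[PatientRecord], catalog: TestCatalog
) -> PeriodSummary:
    """Summarise one cohort; all records must share indication and period."""
    if not records:
        raise ValidationError("cannot summarise an empty cohort")
    indications = {r.indication for r in records}
    periods = {r.period for r in records}
    if len(indications) > 1 or len(periods) > 1:
        raise ValidationError(
            "records mix indications or periods: "
            f"{sorted(indications)} / {sorted(periods)}"
        )
    n = len(records)
    counts = np.array([len(r.tests) for r in records], dtype=float)
    costs = np.array(
        [sum(catalog.unit_cost(t) for t in r.tests) for r in records]
    )
    unit_costs = np.array(
        [catalog.unit_cost(t) for r in records for t in r.tests]
    )
    mutations = np.array([r.mutation_count for r in records], dtype=float)
    categories = sorted({c for r in records for c in r.category_flags})
    category_counts = {}
    for cat in categories:
        k = sum(bool(r.category_flags.get(cat, False)) for r in records)
        category_counts[cat] = (k, k / n)
    return PeriodSummary(
        indication=indications.pop(),
        period=periods.pop(),
        n_patients=n,
        tests_per_patient=SummaryStat(counts.mean(), counts.min(), counts.max()),
        cost_per_patient=SummaryStat(costs.mean(), costs.min(), costs.max()),
        cost_per_test=SummaryStat(
            unit_costs.mean(), unit_costs.min(), unit_costs.max()
        ),
        mutations_per_patient=SummaryStat(
            mutations.mean(), mutations.min(), mutations.max()
        ),
        category_counts=category_counts,
    )


def select_test(variable_kind: str, normal: bool) -> str:
    """Which two-group test applies: t, Mann–Whitney, or Fisher."""
    if variable_kind == "binary":
        return "fisher"
    if variable_kind == "continuous":
        return "t" if normal else "mann_whitney"
    raise ValidationError(f"unknown variable kind {variable_kind!r}")


def _is_normal(x: np.ndarray, alpha: float) -> bool:
    """Shapiro–Wilk normality screen; degenerate samples count as non-normal."""
    if len(x) < 3 or np.ptp(x) == 0:
        return False
    return stats.shapiro(x).pvalue > alpha


def _continuous_values(
    records: Sequence[PatientRecord], catalog: TestCatalog, variable: str
) -> np.ndarray:
    if variable == "tests_per_patient":
        return np.array([len(r.tests) for r in records], dtype=float)
    if variable == "cost_per_patient":
        return np.array(
            [sum(catalog.unit_cost(t) for t in r.tests) for r in records]
        )
    if variable == "cost_per_test":
        return np.array(
            [
                sum(catalog.unit_cost(t) for t in r.tests) / len(r.tests)
                for r in records
            ]
        )
    if variable == "mutations_per_patient":
        return np.array([r.mutation_count for r in records], dtype=float)
    raise ValidationError(f"unknown continuous variable {variable!r}")


def compare_periods(
    before: Sequence[PatientRecord],
    after: Sequence[PatientRecord],
    catalog: TestCatalog,
    *,
    alpha: float = 0.05,
    normality_alpha: float = 0.05,
) -> ComparisonResult:
    """Between-period tests for every continuous variable and category flag.

    Continuous variables are screened for normality per group before choosing
    between t-test and Mann–Whitney; binary flags go into 2×2 Fisher tables.
    A variable with zero variance in both groups is marked degenerate and its
    p-value omitted.
    """
    if not before or not after:
        raise ValidationError("both periods need at least one record")
    comparisons: dict[str, VariableComparison] = {}
    for variable in CONTINUOUS_VARIABLES:
        x = _continuous_values(before, catalog, variable)
        y = _continuous_values(after, catalog, variable)
        if np.ptp(x) == 0 and np.ptp(y) == 0:
            comparisons[variable] = VariableComparison(
                variable, "continuous", "none", None, None, degenerate=True
            )
            continue
        normal = _is_normal(x, normality_alpha) and _is_normal(y, normality_alpha)
        test = select_test("continuous", normal)
        if test == "t":
            p = stats.ttest_ind(x, y).pvalue
        else:
            p = stats.mannwhitneyu(x, y, alternative="two-sided").pvalue
        comparisons[variable] = VariableComparison(
            variable, "continuous", test, float(p), bool(p < alpha)
        )
    categories = sorted(
        {c for r in (*before, *after) for c in r.category_flags}
    )
    for cat in categories:
        a = sum(bool(r.category_flags.get(cat, False)) for r in before)
        b = sum(bool(r.category_flags.get(cat, False)) for r in after)
        table = [[a, len(before) - a], [b, len(after) - b]]
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        comparisons[cat] = VariableComparison(
            cat, "binary", "fisher", p, bool(p < alpha)
        )
    return ComparisonResult(comparisons=comparisons, alpha=alpha)


def annualize(
    records: Sequence[PatientRecord],
    observation_months: float,
    catalog: TestCatalog,
) -> tuple[int, dict[str, float]]:
    """Extrapolate an observation window to a full year.

    Returns the yearly patient count (rounded) and the yearly population
    cost per period (yearly patients × that period's mean cost per patient),
    assuming the window's intake rate is representative of the whole year.
    """
    if observation_months <= 0:
        raise ValidationError("observation_months must be positive")
    if not records:
        raise ValidationError("cannot annualize zero patients")
    yearly_patients = round_half_away(len(records) / observation_months * 12)
    costs_per_period: dict[str, float] = {}
    for period in PERIODS:
        period_records = [r for r in records if r.period == period]
        if not period_records:
            continue
        mean_cost = float(
            np.mean(
                [sum(catalog.unit_cost(t) for t in r.tests) for r in period_records]
            )
        )
        costs_per_period[period] = yearly_patients * mean_cost
    return yearly_patients, costs_per_period


def institutional_budget_impact(
    before_summary: PeriodSummary,
    after_summary: PeriodSummary,
    yearly_patients: int,
) -> BudgetImpact:
    """Institutional budget impact of the NGS introduction.

    Per-patient delta is the change in mean test cost; the population delta
    scales it by the yearly patient count (unrounded; rounding at reporting).
    """
    if before_summary.indication != after_summary.indication:
        raise ValidationError("summaries compare different indications")
    per_patient = (
        after_summary.cost_per_patient.mean - before_summary.cost_per_patient.mean
    )
    return BudgetImpact(
        from_timeframe=before_summary.period,
        to_timeframe=after_summary.period,
        indication=before_summary.indication,
        per_patient_delta=per_patient,
        population_delta=yearly_patients * per_patient,
    )


# ---------------------------------------------------------------------------
# CSV round-trip for patient records

_BASE_COLUMNS = ("patient_id", "indication", "period", "tests", "mutation_count")


def records_to_csv(records: Sequence[PatientRecord], path: str | Path) -> None:
    """Write records as CSV; tests semicolon-separated, one column per flag."""
    categories = sorted({c for r in records for c in r.category_flags})
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow([*_BASE_COLUMNS, *categories])
        for r in records:
            writer.writerow(
                [
                    r.patient_id,
                    r.indication,
                    r.period,
                    ";".join(r.tests),
                    r.mutation_count,
                    *(int(bool(r.category_flags.get(c, False))) for c in categories),
                ]
            )


def records_from_csv(path: str | Path) -> list[PatientRecord]:
    """Read records written by :func:`records_to_csv`."""
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        categories = [c for c in (reader.fieldnames or []) if c not in _BASE_COLUMNS]
        for row in reader:
            records.append(
                PatientRecord(
                    patient_id=row["patient_id"],
                    indication=row["indication"],
                    period=row["period"],
                    tests=tuple(row["tests"].split(";")),
                    mutation_count=int(row["mutation_count"]),
                    category_flags={c: bool(int(row[c])) for c in categories},
                )
            )
    return records
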