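"""One-way sensitivity analysis with tornado-ordered output.

Parameters are varied one at a time between a low and a high value while
everything else stays at base; each parameter yields the model outcome at
the two extremes and the resulting range width.  Sorting entries by
descending width gives the tornado diagram.

Two concrete models are provided:

* :func:`future_bia_model` — the population budget impact of moving from the
  current to the future diagnostic practice, with prices (or the specialised-
  care share) perturbed *in the future time frame only*; the current frame
  keeps its base prices.  This is the only reading under which the published
  swing of the small-panel price bar is reproduced.
* :func:`current_cost_sensitivity` — the per-patient test cost in the current
  specialised-care setting: ABC cost of the small panel under the run plan
  plus the additional single-gene tests still required next to it.

The default relative range is ±20%.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Iterable, Mapping, Sequence

from .abc_costing import PanelCostSpec, RunPlan, cost_per_sample
from .bia import BiaInputs, Scenario, population_cost
from .errors import PanelCostError, ValidationError

DEFAULT_RELATIVE_RANGE = 0.20


@dataclass(frozen=True)
class SensitivityParam:
    """One model input with its base value and plausible extremes."""

    name: str
    base_value: float
    low: float
    high: float
    binding: str | None = None

    def __post_init__(self) -> None:
        if not self.low <= self.base_value <= self.high:
            raise ValidationError(
                f"parameter {self.name!r}: require low <= base <= high, "
                f"got {self.low} / {self.base_value} / {self.high}"
            )


def relative_param(
    name: str,
    base_value: float,
    rel_range: float = DEFAULT_RELATIVE_RANGE,
    binding: str | None = None,
) -> SensitivityParam:
    """A parameter varied by ±``rel_range`` relative to its base value."""
    return SensitivityParam(
        name=name,
        base_value=base_value,
        low=base_value * (1 - rel_range),
        high=base_value * (1 + rel_range),
        binding=binding,
    )


@dataclass(frozen=True)
class TornadoEntry:
    """Model outcomes at a parameter's two extremes."""

    name: str
    outcome_at_low: float
    outcome_at_high: float

    @property
    def width(self) -> float:
        return abs(self.outcome_at_high - self.outcome_at_low)


def one_way(
    model: Callable[[float], float], param: SensitivityParam
) -> TornadoEntry:
    """Evaluate a one-parameter model at the parameter's extremes."""
    outcomes = []
    for value in (param.low, param.high):
        try:
            outcomes.append(model(value))
        except PanelCostError as exc:
            raise type(exc)(
                f"model failed at {param.name!r} = {value}: {exc}"
            ) from exc
    return TornadoEntry(param.name, outcomes[0], outcomes[1])


def tornado(
    model: Callable[[str, float], float],
    params: Sequence[SensitivityParam],
) -> list[TornadoEntry]:
    """One-way analysis over several parameters, sorted by descending width.

    The sort is stable: ties keep the input parameter order.
    """
    if not params:
        raise ValidationError("tornado needs at least one parameter")
    entries = [
        one_way(lambda v, p=p: model(p.name, v), p) for p in params
    ]
    return sorted(entries, key=lambda e: -e.width)


# ---------------------------------------------------------------------------
# Concrete models


def future_bia_model(
    inputs: BiaInputs,
    indication: str,
    *,
    from_timeframe: str = "current_2015",
    to_timeframe: str = "future_2020",
) -> Callable[[str, float], float]:
    """Population budget impact with future-frame-only perturbations.

    Recognised parameter names: ``tgp_price`` (the small-panel unit price),
    ``wgs_price``, and ``specialised_share`` (the fraction of patients in
    specialised care, peripheral renormalised to keep shares summing to 1).
    """
    base_cost = inputs.population_cost(from_timeframe, indication)

    def outcome(param_name: str, value: float) -> float:
        catalog = inputs.catalog
        scenarios: Iterable[Scenario] = inputs.scenarios
        if param_name == "tgp_price":
            catalog = catalog.with_price("tgp_small", value)
        elif param_name == "wgs_price":
            catalog = catalog.with_price("wgs", value)
        elif param_name == "specialised_share":
            if not 0 <= value <= 1:
                raise ValidationError("specialised share must lie in [0, 1]")
            scenarios = tuple(
                replace(
                    s,
                    patient_share=value if s.stratum == "specialised" else 1 - value,
                )
                if s.timeframe == to_timeframe and s.indication == indication
                else s
                for s in inputs.scenarios
            )
        else:
            raise ValidationError(f"unknown future-BIA parameter {param_name!r}")
        future_cost = population_cost(
            to_timeframe, indication, scenarios, catalog, inputs.populations
        )
        return future_cost - base_cost

    return outcome


def default_future_params(
    inputs: BiaInputs,
    indication: str,
    rel_range: float = DEFAULT_RELATIVE_RANGE,
) -> list[SensitivityParam]:
    """The three future-BIA parameters at their configured base values."""
    specialised_share = next(
        s.patient_share
        for s in inputs.scenarios
        if s.timeframe == "future_2020"
        and s.indication == indication
        and s.stratum == "specialised"
    )
    return [
        relative_param("tgp_price", inputs.catalog.unit_cost("tgp_small"), rel_range),
        relative_param("wgs_price", inputs.catalog.unit_cost("wgs"), rel_range),
        relative_param("specialised_share", specialised_share, rel_range),
    ]


DEFAULT_ADDITIONAL_TESTS = ("fragment_analysis", "sanger", "fish")


def current_cost_sensitivity(
    abc_spec: PanelCostSpec,
    catalog,
    base_plan: RunPlan | None = None,
    params: Mapping[str, SensitivityParam] | None = None,
    additional_tests: Sequence[str] = DEFAULT_ADDITIONAL_TESTS,
) -> list[TornadoEntry]:
    """Tornado for the current-situation per-patient test cost.

    The outcome is the ABC cost per sample of the panel plus the unit costs
    of the first ``n_additional_tests`` tests of ``additional_tests``.
    Perturbable parameters (keys of ``params``): ``samples_per_run``,
    ``runs_per_week``, ``fill_fraction``, ``n_additional_tests``.  Published
    ranges for this analysis are not fully documented, so callers supply
    explicit low/high values; :func:`default_current_cost_params` packages
    the base values with in-house plausible ranges.
    """
    if base_plan is None:
        base_plan = RunPlan(samples_per_run=24, runs_per_week=1.0, fill_fraction=0.85)
    if params is None:
        params = default_current_cost_params()

    def outcome(param_name: str, value: float) -> float:
        plan = base_plan
        n_additional = len(additional_tests)
        if param_name == "samples_per_run":
            plan = replace(plan, samples_per_run=int(round(value)))
        elif param_name == "runs_per_week":
            plan = replace(plan, runs_per_week=value)
        elif param_name == "fill_fraction":
            plan = replace(plan, fill_fraction=value)
        elif param_name == "n_additional_tests":
            n_additional = int(round(value))
            if not 0 <= n_additional <= len(additional_tests):
                raise ValidationError(
                    f"n_additional_tests must lie in [0, {len(additional_tests)}]"
                )
        else:
            raise ValidationError(f"unknown cost parameter {param_name!r}")
        extra = sum(
            catalog.unit_cost(name) for name in additional_tests[:n_additional]
        )
        return cost_per_sample(abc_spec, plan).cost_per_patient_sample + extra

    return tornado(outcome, list(params.values()))


def default_current_cost_params() -> dict[str, SensitivityParam]:
    """Base values with plausible in-house ranges for the current-cost tornado."""
    return {
        "samples_per_run": SensitivityParam("samples_per_run", 24, 4, 48),
        "runs_per_week": SensitivityParam("runs_per_week", 1.0, 1.0, 5.0),
        "fill_fraction": SensitivityParam("fill_fraction", 0.85, 0.5, 1.0),
        "n_additional_tests": SensitivityParam("n_additional_tests", 3, 0, 3),
    }
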