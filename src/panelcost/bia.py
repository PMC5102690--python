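"""Budget impact analysis (BIA) for molecular diagnostics, ISPOR-style.

The model compares three diagnostic-practice snapshots — old (2012),
current (2015) and future (2020) — for two indications (stage-IV NSCLC and
stage-IV melanoma) across two hospital strata (peripheral vs specialised
care).  Each time frame × indication × stratum cell carries a bundle of
molecular tests (with applicability fractions for tests only a share of
patients receive); per-patient cost is the stratum-share-weighted bundle
cost, and population cost scales it by the yearly number of newly diagnosed
stage-IV patients.  The budget impact between two frames is the difference
of (unrounded) costs, positive meaning a cost increase.

Fractional applicability is an expected cost per patient, not patient-level
sampling: the BIA is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import CatalogError, ConfigurationError, ValidationError
from .rounding import round_half_away

TIMEFRAMES = ("old_2012", "current_2015", "future_2020")
INDICATIONS = ("nsclc", "melanoma")
STRATA = ("peripheral", "specialised")

_SHARE_TOL = 1e-9


@dataclass(frozen=True)
class TestCatalog:
    """Unit costs (euros) per molecular diagnostic test."""

    entries: Mapping[str, float]

    def __post_init__(self) -> None:
        for name, cost in self.entries.items():
            if cost <= 0:
                raise ValidationError(f"unit cost for {name!r} must be positive")

    def unit_cost(self, name: str) -> float:
        try:
            return self.entries[name]
        except KeyError:
            raise CatalogError(f"unknown test {name!r} in catalog") from None

    def with_price(self, name: str, price: float) -> "TestCatalog":
        """A new catalog with one entry repriced."""
        self.unit_cost(name)  # raise early on unknown names
        updated = dict(self.entries)
        updated[name] = price
        return TestCatalog(updated)

    def __contains__(self, name: str) -> bool:
        return name in self.entries


@dataclass(frozen=True)
class TestBundle:
    """Tests one patient in a scenario cell receives, with applicability fractions."""

    items: Sequence[tuple[str, float]]

    def __post_init__(self) -> None:
        for name, fraction in self.items:
            if not 0 < fraction <= 1:
                raise ValidationError(
                    f"applicability fraction for {name!r} must lie in (0, 1]"
                )


@dataclass(frozen=True)
class Scenario:
    """One time frame × indication × hospital stratum cell of the model."""

    timeframe: str
    indication: str
    stratum: str
    bundle: TestBundle
    patient_share: float

    def __post_init__(self) -> None:
        if not 0 <= self.patient_share <= 1:
            raise ValidationError("patient_share must lie in [0, 1]")


@dataclass(frozen=True)
class PopulationFrame:
    """Yearly number of newly diagnosed stage-IV patients for a frame."""

    timeframe: str
    indication: str
    patients_per_year: int

    def __post_init__(self) -> None:
        if self.patients_per_year <= 0:
            raise ValidationError("patients_per_year must be positive")


@dataclass(frozen=True)
class BudgetImpact:
    """Cost delta between two frames; positive means a cost increase."""

    from_timeframe: str
    to_timeframe: str
    indication: str
    per_patient_delta: float
    population_delta: float

    @property
    def per_patient_rounded(self) -> int:
        return round_half_away(self.per_patient_delta)

    @property
    def population_rounded(self) -> int:
        return round_half_away(self.population_delta)


def bundle_cost(bundle: TestBundle, catalog: TestCatalog) -> float:
    """Expected cost of a test bundle: Σ fraction × unit cost, unrounded."""
    return sum(fraction * catalog.unit_cost(name) for name, fraction in bundle.items)


def _frame_scenarios(
    timeframe: str, indication: str, scenarios: Iterable[Scenario]
) -> list[Scenario]:
    frame = [
        s for s in scenarios
        if s.timeframe == timeframe and s.indication == indication
    ]
    if not frame:
        raise ConfigurationError(
            f"no scenarios configured for {indication}/{timeframe}"
        )
    total_share = sum(s.patient_share for s in frame)
    if abs(total_share - 1.0) > _SHARE_TOL:
        raise ValidationError(
            f"stratum shares for {indication}/{timeframe} sum to "
            f"{total_share:.6f}, expected 1"
        )
    return frame


def weighted_cost_per_patient(
    timeframe: str,
    indication: str,
    scenarios: Iterable[Scenario],
    catalog: TestCatalog,
) -> float:
    """Stratum-share-weighted per-patient diagnostic cost for one frame."""
    frame = _frame_scenarios(timeframe, indication, scenarios)
    return sum(s.patient_share * bundle_cost(s.bundle, catalog) for s in frame)


def population_cost(
    timeframe: str,
    indication: str,
    scenarios: Iterable[Scenario],
    catalog: TestCatalog,
    frames: Iterable[PopulationFrame],
) -> float:
    """Yearly national diagnostic cost: patients per year × per-patient cost."""
    for frame in frames:
        if frame.timeframe == timeframe and frame.indication == indication:
            return frame.patients_per_year * weighted_cost_per_patient(
                timeframe, indication, scenarios, catalog
            )
    raise ConfigurationError(
        f"no population frame configured for {indication}/{timeframe}"
    )


def budget_impact(
    from_timeframe: str,
    to_timeframe: str,
    indication: str,
    scenarios: Iterable[Scenario],
    catalog: TestCatalog,
    frames: Iterable[PopulationFrame],
) -> BudgetImpact:
    """Budget impact of moving from one time frame to another.

    Both deltas are differences of unrounded values; rounding happens only
    in the reporting properties.
    """
    scenarios = list(scenarios)
    frames = list(frames)
    per_patient = weighted_cost_per_patient(
        to_timeframe, indication, scenarios, catalog
    ) - weighted_cost_per_patient(from_timeframe, indication, scenarios, catalog)
    population = population_cost(
        to_timeframe, indication, scenarios, catalog, frames
    ) - population_cost(from_timeframe, indication, scenarios, catalog, frames)
    return BudgetImpact(
        from_timeframe=from_timeframe,
        to_timeframe=to_timeframe,
        indication=indication,
        per_patient_delta=per_patient,
        population_delta=population,
    )


def wgs_price_projection(
    usd_per_genome: float,
    genomes_per_patient: int,
    reduction_fraction: float,
    usd_to_eur: float,
) -> float:
    """Projected per-patient WGS cost in euros.

    A reliable diagnostic WGS result takes several genome sequences per
    patient (tumour in triplicate plus a germline reference, i.e. four);
    sequencing prices are assumed to fall by ``reduction_fraction`` over the
    projection horizon.
    """
    if usd_per_genome <= 0 or genomes_per_patient <= 0 or usd_to_eur <= 0:
        raise ValidationError("projection arguments must be positive")
    if not 0 <= reduction_fraction < 1:
        raise ValidationError("reduction_fraction must lie in [0, 1)")
    return usd_per_genome * genomes_per_patient * (1 - reduction_fraction) * usd_to_eur


@dataclass(frozen=True)
class BiaInputs:
    """A complete, validated BIA model: catalog, scenario cells and populations."""

    catalog: TestCatalog
    scenarios: tuple[Scenario, ...]
    populations: tuple[PopulationFrame, ...] = field(default_factory=tuple)

    def cost_per_patient(self, timeframe: str, indication: str) -> float:
        return weighted_cost_per_patient(
            timeframe, indication, self.scenarios, self.catalog
        )

    def population_cost(self, timeframe: str, indication: str) -> float:
        return population_cost(
            timeframe, indication, self.scenarios, self.catalog, self.populations
        )

    def budget_impact(
        self, from_timeframe: str, to_timeframe: str, indication: str
    ) -> BudgetImpact:
        return budget_impact(
            from_timeframe,
            to_timeframe,
            indication,
            self.scenarios,
            self.catalog,
            self.populations,
        )

    def with_catalog(self, catalog: TestCatalog) -> "BiaInputs":
        return BiaInputs(catalog, self.scenarios, self.populations)
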