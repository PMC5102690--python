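"""Configuration loading and validation for the packaged fixtures.

Everything the model consumes ships as structured YAML inside
``panelcost.data``: activity schedules with calibrated personnel rates,
canonical panel cost decompositions, the national BIA scenario file, the
synthetic cohort profiles and the institutional case-study aggregates.
External files in the same shapes load through the same functions.

Validation is schema-first (pydantic): stratum shares must sum to one per
time frame × indication, prices must be positive, bundles must resolve in
the catalog, and run plans must respect panel capacity — all checked before
any computation runs.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Literal, Mapping

import pydantic
import yaml

from .abc_costing import ActivityStep, PanelCostSpec, PersonnelRate
from .bia import BiaInputs, PopulationFrame, Scenario, TestBundle, TestCatalog
from .errors import ConfigurationError
from .synthetic import CohortProfile

_DATA = resources.files("panelcost.data")

BIA_VARIANTS = ("netherlands", "netherlands_table2", "netherlands_printed")


def _load_yaml(source: str | Path | Mapping) -> dict:
    if isinstance(source, Mapping):
        return dict(source)
    path = Path(source)
    if path.exists():
        return yaml.safe_load(path.read_text())
    try:
        return yaml.safe_load((_DATA / f"{source}.yaml").read_text())
    except FileNotFoundError:
        raise ConfigurationError(f"no such config file or fixture: {source!r}") from None


# ---------------------------------------------------------------------------
# Schemas


class _BundleItem(pydantic.BaseModel):
    test: str
    fraction: float = pydantic.Field(gt=0, le=1)


class _ScenarioModel(pydantic.BaseModel):
    timeframe: Literal["old_2012", "current_2015", "future_2020"]
    indication: Literal["nsclc", "melanoma"]
    stratum: Literal["peripheral", "specialised"]
    patient_share: float = pydantic.Field(ge=0, le=1)
    bundle: list[_BundleItem]


class _PopulationModel(pydantic.BaseModel):
    timeframe: Literal["old_2012", "current_2015", "future_2020"]
    indication: Literal["nsclc", "melanoma"]
    patients_per_year: int = pydantic.Field(gt=0)


class _BiaConfigModel(pydantic.BaseModel):
    catalog: dict[str, float]
    scenarios: list[_ScenarioModel]
    populations: list[_PopulationModel] = []

    @pydantic.model_validator(mode="after")
    def _check(self) -> "_BiaConfigModel":
        for name, price in self.catalog.items():
            if price <= 0:
                raise ValueError(f"catalog.{name}: price must be positive")
        for i, s in enumerate(self.scenarios):
            for item in s.bundle:
                if item.test not in self.catalog:
                    raise ValueError(
                        f"scenarios[{i}].bundle: unknown test {item.test!r}"
                    )
        shares: dict[tuple[str, str], float] = {}
        for s in self.scenarios:
            key = (s.timeframe, s.indication)
            shares[key] = shares.get(key, 0.0) + s.patient_share
        for (timeframe, indication), total in shares.items():
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"stratum shares for {indication}/{timeframe} sum to {total}"
                )
        return self


def load_bia_inputs(source: str | Path | Mapping = "netherlands") -> BiaInputs:
    """Load and validate a BIA scenario file or packaged variant.

    Packaged variants: ``netherlands`` (canonical, calibrated unit costs),
    ``netherlands_table2`` (NSCLC current/peripheral at the published table
    cell of 559 EUR, as a combined EGFR+ALK entry), ``netherlands_printed``
    (Sanger and fragment analysis at the publicly printed 295 EUR).
    """
    if source == "netherlands_table2":
        raw = _load_yaml("netherlands_bia")
        raw["catalog"]["egfr_alk_pair"] = 559.0
        for scenario in raw["scenarios"]:
            if (
                scenario["timeframe"] == "current_2015"
                and scenario["indication"] == "nsclc"
                and scenario["stratum"] == "peripheral"
            ):
                scenario["bundle"] = [{"test": "egfr_alk_pair", "fraction": 1.0}]
    elif source == "netherlands_printed":
        raw = _load_yaml("netherlands_bia")
        raw["catalog"]["sanger"] = 295.0
        raw["catalog"]["fragment_analysis"] = 295.0
    elif source == "netherlands":
        raw = _load_yaml("netherlands_bia")
    else:
        raw = _load_yaml(source)
    try:
        model = _BiaConfigModel.model_validate(raw)
    except pydantic.ValidationError as exc:
        raise ConfigurationError(str(exc)) from None
    scenarios = tuple(
        Scenario(
            timeframe=s.timeframe,
            indication=s.indication,
            stratum=s.stratum,
            patient_share=s.patient_share,
            bundle=TestBundle(tuple((i.test, i.fraction) for i in s.bundle)),
        )
        for s in model.scenarios
    )
    populations = tuple(
        PopulationFrame(p.timeframe, p.indication, p.patients_per_year)
        for p in model.populations
    )
    return BiaInputs(TestCatalog(model.catalog), scenarios, populations)


# ---------------------------------------------------------------------------
# ABC fixtures

PANEL_SPEC_NAMES = (
    "small_tgp_miseq",
    "small_tgp_hiseq",
    "medium_tgp_miseq",
    "medium_tgp_hiseq",
)


def load_panel_spec(panel: str, platform: str) -> PanelCostSpec:
    """Canonical cost decomposition for one panel × platform."""
    raw = _load_yaml("panel_specs")["panel_specs"]
    key = f"{panel}_{platform}"
    if key not in raw:
        raise ConfigurationError(
            f"no packaged panel spec {key!r}; choose from {PANEL_SPEC_NAMES}"
        )
    return PanelCostSpec(**raw[key])


def load_personnel_rates() -> list[PersonnelRate]:
    raw = _load_yaml("activity_schedules")["rates"]
    return [PersonnelRate(role, rate) for role, rate in raw.items()]


def load_activity_schedule(panel: str, platform: str) -> list[ActivityStep]:
    """Activity schedule for one panel, with platform-dependent lines resolved."""
    raw = _load_yaml("activity_schedules")["panels"]
    if panel not in raw:
        raise ConfigurationError(f"no packaged schedule for panel {panel!r}")
    panel_raw = raw[panel]
    if platform not in panel_raw["run_material"]:
        raise ConfigurationError(f"no platform {platform!r} for panel {panel!r}")
    substitutions = {
        "run_material": panel_raw["run_material"][platform],
        "sequencer_equipment": panel_raw["sequencer_equipment"][platform],
    }
    steps = []
    for entry in panel_raw["steps"]:
        fields = {
            key: substitutions.get(value, value) if isinstance(value, str) else value
            for key, value in entry.items()
        }
        fields["label"] = entry["label"]
        steps.append(ActivityStep(**fields))
    return steps


def panel_max_samples(panel: str, platform: str) -> int:
    return int(_load_yaml("activity_schedules")["panels"][panel]["max_samples_per_run"][platform])


# ---------------------------------------------------------------------------
# Case-study fixtures


def load_cohort_profile(name: str) -> CohortProfile:
    """A packaged synthetic-cohort profile (e.g. ``nsclc_before``)."""
    profiles = _load_yaml("cohort_profiles")["profiles"]
    if name not in profiles:
        raise ConfigurationError(
            f"no packaged cohort profile {name!r}; choose from {sorted(profiles)}"
        )
    return CohortProfile(**profiles[name])


def cohort_profile_names() -> list[str]:
    return sorted(_load_yaml("cohort_profiles")["profiles"])


def load_case_aggregates() -> dict:
    """Published institutional aggregates (period costs, yearly patients)."""
    return _load_yaml("case_aggregates")


# ---------------------------------------------------------------------------
# Pipeline run configuration


class RunConfig(pydantic.BaseModel):
    """Fully validated configuration for an end-to-end reporting run."""

    scenario_config: str = "netherlands"
    panels: list[str] = list(PANEL_SPEC_NAMES)
    output_dir: Path = Path("panelcost-output")
    seed: int = 0
    rounding: Literal["whole_euro", "none"] = "whole_euro"
    log_level: Literal["DEBUG", "INFO", "WARNING", "ERROR"] = "INFO"

    model_config = pydantic.ConfigDict(extra="forbid")


def validate_config(raw: Mapping | str | Path) -> RunConfig:
    """Resolve and schema-check a pipeline configuration.

    Referenced fixtures are loaded eagerly so that share sums, price
    positivity and capacity constraints all surface here, with their path
    in the file, before any computation.
    """
    data = _load_yaml(raw) if not isinstance(raw, Mapping) else dict(raw)
    try:
        config = RunConfig.model_validate(data)
    except pydantic.ValidationError as exc:
        raise ConfigurationError(str(exc)) from None
    load_bia_inputs(config.scenario_config)  # validates shares/prices/bundles
    for key in config.panels:
        panel, _, platform = key.rpartition("_")
        load_panel_spec(panel, platform)
    return config
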