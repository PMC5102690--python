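import pytest

from panelcost import RunPlan, load_bia_inputs, load_panel_spec

BASE_PLAN = RunPlan(samples_per_run=24, runs_per_week=1.0, fill_fraction=0.85)


@pytest.fixture(scope="session")
def inputs():
    """The canonical Dutch national BIA model."""
    return load_bia_inputs("netherlands")


@pytest.fixture(scope="session")
def catalog(inputs):
    return inputs.catalog


@pytest.fixture(scope="session")
def small_miseq():
    return load_panel_spec("small_tgp", "miseq")


@pytest.fixture(scope="session")
def base_plan():
    return BASE_PLAN
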