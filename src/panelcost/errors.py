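"""Exception hierarchy shared across the package."""


class PanelCostError(Exception):
    """Base class for all panelcost errors."""


class ValidationError(PanelCostError):
    """An input value violates a domain invariant."""


class ConfigurationError(PanelCostError):
    """A configuration file or fixture is incomplete or inconsistent."""


class CapacityError(PanelCostError):
    """A run plan exceeds the physical capacity of a panel/platform."""


class CatalogError(PanelCostError):
    """A test name cannot be resolved against the unit-cost catalog."""
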