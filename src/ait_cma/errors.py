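"""Exception hierarchy shared across the model."""


class CostModelError(Exception):
    """Base class for all model errors."""


class InvalidParameterError(CostModelError, ValueError):
    """A numeric parameter violates its domain (e.g. non-positive interval)."""


class ModalityError(CostModelError, ValueError):
    """An operation received a schedule/scheme of the wrong treatment modality."""


class ConfigurationError(CostModelError, ValueError):
    """A configuration is incomplete or inconsistent (e.g. missing tariff code)."""


class ScenarioOverrideError(ConfigurationError):
    """A scenario override path does not resolve against the analysis config."""
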