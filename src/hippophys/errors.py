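"""Exception hierarchy shared across the package."""


class HippophysError(Exception):
    """Base class for all package-specific errors."""


class ClampModeError(HippophysError):
    """An operation received a sweep recorded in the wrong clamp mode."""


class IntegrationError(HippophysError):
    """The membrane-equation integrator produced a non-finite state."""


class ThresholdUndefinedError(HippophysError):
    """No sample on the rising phase satisfies the dV/dt criterion."""


class RheobaseNotFoundError(HippophysError):
    """No sweep in the protocol elicited an action potential."""


class EmptyMorphologyError(HippophysError):
    """Generator parameters produced a tree with no neurite."""


class SWCParseError(HippophysError):
    """Malformed SWC content (orphan node, duplicate id, cycle, bad field)."""


class ConfigError(HippophysError):
    """Invalid configuration value."""


class DataError(HippophysError):
    """Physically impossible or inconsistent input data."""
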