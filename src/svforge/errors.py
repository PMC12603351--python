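"""Exception hierarchy shared across the simulator."""


class SVForgeError(Exception):
    """Base class for all svforge errors."""


class GrammarError(SVForgeError):
    """Raised when a rearrangement expression cannot be parsed."""


class ConfigError(SVForgeError):
    """Raised when the YAML configuration is invalid."""


class PlacementError(SVForgeError):
    """Raised when an SV cannot be placed under its constraints."""


class ImportError_(SVForgeError):
    """Raised when a VCF of pre-specified SVs cannot be imported."""


class FixtureError(SVForgeError):
    """Raised when a fixture specification is infeasible."""
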