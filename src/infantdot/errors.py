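"""Exception hierarchy shared across the pipeline."""


class InfantDotError(Exception):
    """Base class for all package-specific errors."""


class DimensionError(InfantDotError):
    """Grid or array shapes are inconsistent with the request."""


class PlacementError(InfantDotError):
    """An optode could not be placed on the scalp surface."""


class ConfigError(InfantDotError):
    """A configuration value violates its contract."""


class SpecError(InfantDotError):
    """An activation/simulation specification is invalid."""


class ParseError(InfantDotError):
    """A recording file could not be parsed."""


class ValidationError(InfantDotError):
    """A data structure violates one of its invariants."""


class EstimationError(InfantDotError):
    """A statistical estimate could not be computed (e.g. rank deficiency)."""
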