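"""Exception types shared across the package."""


class NeurodynError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(NeurodynError):
    """A parameter combination that cannot produce a valid analysis."""


class AlignmentError(NeurodynError):
    """Streams or traces that must share coordinates/cadence/length do not."""


class DegenerateInputError(NeurodynError):
    """Input whose values cannot support the requested discretization."""


class StratumError(NeurodynError):
    """An aggregation stratum selected no streams."""
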