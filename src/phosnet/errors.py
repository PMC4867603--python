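"""Exception hierarchy shared across the pipeline."""


class PhosnetError(ValueError):
    """Base class for all phosnet errors."""


class ConfigurationError(PhosnetError):
    """Invalid simulation or pipeline configuration."""


class InputFormatError(PhosnetError):
    """Malformed input table (names the offending row where possible)."""


class ParameterError(PhosnetError):
    """Operation called with inconsistent or out-of-range parameters."""


class DesignError(PhosnetError):
    """Invalid experimental design (e.g. a condition with no samples)."""


class ConsistencyError(PhosnetError):
    """Cross-table references that do not resolve."""
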