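"""Exception hierarchy shared across modules."""


class GenestrataError(Exception):
    """Base class for all package errors."""


class TableFormatError(GenestrataError):
    """A tabular input file is malformed (missing columns, bad types)."""


class ValidationError(GenestrataError):
    """Data violates a domain invariant (e.g. end < start, duplicate ids)."""


class ConfigurationError(GenestrataError):
    """A configuration value is missing, inconsistent, or infeasible."""


class NumericalError(GenestrataError):
    """An iterative numerical procedure failed; message carries diagnostics."""
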