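"""Exception hierarchy shared across the package."""


class DcphaError(Exception):
    """Base class for all package errors."""


class DimensionError(DcphaError, ValueError):
    """Input shapes are inconsistent with each other or with a contract."""


class ParameterError(DcphaError, ValueError):
    """A scalar parameter is outside its valid range."""


class DegenerateInputError(DcphaError, ValueError):
    """Input is structurally valid but mathematically degenerate
    (e.g. an all-zero code row where cosine similarity is undefined)."""


class ConfigError(DcphaError, ValueError):
    """A configuration object violates its invariants."""


class DataError(DcphaError, ValueError):
    """A dataset violates a structural requirement (empty, unsplittable...)."""


class ContractError(DcphaError, ValueError):
    """An operation was called with input that breaks its usage contract
    (e.g. evaluation on non-binary codes)."""


class ParseError(DcphaError, ValueError):
    """A file could not be parsed; the message names the offending line."""
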