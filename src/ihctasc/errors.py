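"""Exception types raised across the pipeline."""


class IhcTascError(Exception):
    """Base class for all package-specific errors."""


class SpecificationError(IhcTascError, ValueError):
    """A synthetic-data specification violates its invariants."""


class FormatError(IhcTascError, ValueError):
    """An input image or table has the wrong format or shape."""


class ConfigurationError(IhcTascError, ValueError):
    """A configuration object is internally inconsistent."""


class DegenerateRoiError(IhcTascError, ValueError):
    """A region of interest is empty or entirely excluded as artifact."""


class DomainError(IhcTascError, ValueError):
    """A numeric input falls outside its documented domain."""
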