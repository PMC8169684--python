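"""Exception hierarchy shared across the package."""


class HerbiscreenError(Exception):
    """Base class for all package-specific errors."""


class StructureError(HerbiscreenError, ValueError):
    """A structure string could not be parsed or processed.

    Carries the offending input in ``args[0]`` so batch callers can build
    rejection reports.
    """


class ValidationError(HerbiscreenError, ValueError):
    """Input data violate a documented precondition or invariant."""


class ConfigurationError(HerbiscreenError, ValueError):
    """A configuration value (column mapping, override name, scaffold) is invalid."""


class DomainError(HerbiscreenError, ValueError):
    """A numeric argument lies outside the mathematical domain of a formula."""
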