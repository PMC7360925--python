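"""Exception hierarchy.

Every failure mode the library reports deliberately maps onto one of these,
so callers (and the CLI exit-code table) can dispatch on type rather than
message text.
"""


class SymbioError(Exception):
    """Base class for all symbiofba errors."""


class ValidationError(SymbioError):
    """A model or table violates a structural invariant."""


class FormatError(SymbioError):
    """A file could not be parsed in the declared format."""


class AssemblyError(SymbioError):
    """Host and symbiont models could not be merged into a community."""


class ConfigurationError(SymbioError):
    """A requested reaction/metabolite id or option does not resolve."""


class InfeasibleError(SymbioError):
    """An LP that was required to be feasible is not."""
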