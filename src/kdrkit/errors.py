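"""Typed exceptions shared across the package."""


class KdrKitError(Exception):
    """Base class for all kdrkit errors."""


class ValidationError(KdrKitError):
    """Input values violate a domain invariant (negative count, bad frequency...)."""


class FormatError(KdrKitError):
    """A file or table does not follow the expected schema."""


class UsageError(KdrKitError):
    """Caller asked for something the API does not offer (unknown format/model)."""


class MonomorphicLocusError(KdrKitError):
    """Linkage-disequilibrium statistics are undefined when a locus is fixed."""


class UndefinedStatisticError(KdrKitError):
    """The requested statistic is undefined for this table (e.g. OR with a
    doubly-zero margin, Abbott correction at 100% control mortality)."""


class PrimerBindingError(KdrKitError):
    """A primer of the pair finds no binding site on either template strand."""


class AmbiguousProductError(KdrKitError):
    """The primer pair predicts more than one amplification product."""
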