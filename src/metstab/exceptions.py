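"""Error hierarchy for metstab.

All package-raised errors derive from :class:`MetstabError` so callers can
catch everything the library may throw with a single except clause, while the
subclasses preserve the distinction between malformed input files, violated
data invariants, and designs a method cannot handle.
"""


class MetstabError(Exception):
    """Base class for all metstab errors."""


class SchemaError(MetstabError):
    """A required column or field is missing from an input table."""


class IntegrityError(MetstabError):
    """A data invariant is violated (e.g. duplicated observation keys)."""


class InputError(MetstabError):
    """Malformed input values (non-numeric cells, empty files, bad config)."""


class UnsupportedDesignError(MetstabError):
    """The trial design does not meet a method's requirements
    (unbalanced data for AMMI, too few levels, ...)."""


class ConvergenceError(MetstabError):
    """An iterative fit failed to converge; carries diagnostic context."""


class DomainError(MetstabError):
    """A quantity is outside its mathematical domain (e.g. non-positive
    genotypic value in a harmonic mean)."""
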