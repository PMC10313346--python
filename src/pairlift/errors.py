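"""Typed errors raised by pairlift.

Every error a user can trigger from the command line derives from
:class:`PairliftError`, so the CLI can render them as one-line messages
and exit 1; everything else is a bug.
"""


class PairliftError(Exception):
    """Base class for all typed pairlift errors."""


class ChainFormatError(PairliftError):
    """A chain file line violates the UCSC chain grammar."""


class ChainConsistencyError(PairliftError):
    """Chain cursor arithmetic does not reconcile with its header."""


class PairsFormatError(PairliftError):
    """A contact-file line violates its declared dialect."""


class SortOrderError(PairliftError):
    """Records handed to the pairs writer are out of order or off-genome."""


class PlanError(PairliftError):
    """A rearrangement plan is internally inconsistent."""


class ParameterError(PairliftError):
    """A numeric parameter is outside its valid range."""
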