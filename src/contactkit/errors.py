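"""Exception hierarchy for contactkit.

All library-raised errors derive from :class:`ContactKitError` so callers
(and the CLI) can distinguish data problems from programming errors.
"""


class ContactKitError(Exception):
    """Base class for all contactkit data and usage errors."""


class InvalidSchemeError(ContactKitError):
    """A distance bin scheme violates its invariants (e.g. non-monotone edges)."""


class InvalidInputError(ContactKitError):
    """An operation received structurally invalid input (shape/length mismatch,
    empty member list, class mismatch, ...)."""


class RRParseError(ContactKitError):
    """A CASP RR file could not be parsed; the message names the offending line."""


class EmptyLabelError(ContactKitError):
    """Too few structure residues survived reconciliation to build labels."""
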