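"""Exception hierarchy for the nppu package."""


class NPPUError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(NPPUError, ValueError):
    """A numeric input violates a domain precondition (e.g. TE = 0, TL < 1)."""


class MissingDataError(NPPUError, KeyError):
    """A tier policy demands a specific value the record does not carry.

    Tiers are a declared methodological contract: a missing specific field
    fails loudly rather than silently downgrading to a generic default.
    """

    def __str__(self) -> str:  # KeyError quotes its message; undo that
        return self.args[0] if self.args else ""


class SchemaError(NPPUError, ValueError):
    """A table does not conform to the requested schema (missing column,
    unparseable cell, record missing a required field)."""
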