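"""Exception hierarchy shared across the package."""


class CorrdistError(Exception):
    """Base class for all corrdist errors."""


class DegenerateProfileError(CorrdistError):
    """A profile has zero variance (or zero norm) and no correlation is defined.

    Carries the offending item identifier when known so matrix-level
    operations can point at the bad gene/sample.
    """

    def __init__(self, message: str, item_id: str | None = None):
        super().__init__(message)
        self.item_id = item_id


class ValidationError(CorrdistError):
    """Structurally invalid input (shape, identifiers, value ranges)."""
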