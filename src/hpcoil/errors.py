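"""Exception hierarchy for hpcoil.

All package errors derive from :class:`HpcoilError` so callers can catch one
base class; the CLI maps them to exit codes and stderr messages.
"""


class HpcoilError(Exception):
    """Base class for all hpcoil errors."""


class RefDataError(HpcoilError):
    """Packaged or user-supplied reference data violates the schema.

    Carries enough context (file, row, field) to locate the offending value.
    """

    def __init__(self, message, *, file=None, row=None, field=None):
        parts = [message]
        if file is not None:
            parts.append(f"file={file}")
        if row is not None:
            parts.append(f"row={row}")
        if field is not None:
            parts.append(f"field={field}")
        super().__init__(" | ".join(str(p) for p in parts))
        self.file = file
        self.row = row
        self.field = field


class NotFoundError(HpcoilError, KeyError):
    """No reference record exists for the requested residue/atom/variant."""


class AmbiguityError(HpcoilError):
    """Several measurement variants match and no default applies (His pH)."""

    def __init__(self, message, variants=()):
        super().__init__(message)
        self.variants = tuple(variants)


class NotComputableError(HpcoilError):
    """A derived quantity cannot be computed from the stored values."""


class FitError(HpcoilError):
    """Least-squares fitting failed (too few points, rank deficiency...)."""


class NonIdentifiableError(FitError):
    """Model parameters are not identifiable from the data provided."""


class RatioUndefinedError(HpcoilError):
    """B2/B1 requested for a record with B1 = 0."""


class UsageError(HpcoilError, ValueError):
    """The caller passed arguments that violate an operation's contract."""


class ParseError(HpcoilError):
    """A delimited input table could not be parsed."""

    def __init__(self, message, *, file=None, line=None):
        loc = ""
        if file is not None:
            loc += f" [{file}"
            loc += f":{line}]" if line is not None else "]"
        elif line is not None:
            loc += f" [line {line}]"
        super().__init__(message + loc)
        self.file = file
        self.line = line
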