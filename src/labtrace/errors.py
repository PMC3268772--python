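"""Exception hierarchy shared by all subsystems."""


class LimsError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(LimsError):
    """Schema initialization problems (already present, unwritable location)."""


class NotFoundError(LimsError):
    """A referenced record, relation or column does not exist."""


class RuleViolationError(LimsError):
    """A write was rejected by the business-rule checker.

    Carries the full violation list so callers can report every problem
    at once instead of failing on the first.
    """

    def __init__(self, relation, violations):
        self.relation = relation
        self.violations = list(violations)
        detail = "; ".join(f"{v.rule}:{v.column}" for v in self.violations)
        super().__init__(f"rule violations on {relation}: {detail}")


class PermissionDeniedError(LimsError):
    """The active session is not authorized for the attempted action."""


class AuthenticationError(LimsError):
    """Login refused.  Deliberately carries no detail about the cause."""


class ImportError_(LimsError):
    """A bulk import failed; nothing was persisted."""


class ExportError(LimsError):
    """An export could not be produced (bad format, ragged alignment, ...)."""
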