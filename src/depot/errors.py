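"""Exception hierarchy for the depot engine.

Every error raised on a contract violation derives from :class:`DepotError`
so callers (and the CLI) can distinguish domain failures from bugs.
"""


class DepotError(Exception):
    """Base class for all depot domain errors."""


class ValidationError(DepotError):
    """Input violates a documented precondition (bad keys, empty members...)."""


class NotFoundError(DepotError):
    """A referenced unit id does not exist in the metadata graph."""


class CycleError(DepotError):
    """A provenance edge would make a unit its own ancestor.

    ``path`` holds the offending unit-id chain from the proposed output back
    to one of the inputs.
    """

    def __init__(self, message: str, path: list | None = None):
        super().__init__(message)
        self.path = path or []


class CollisionError(DepotError):
    """A context-tree rule maps two or more units to the same path.

    ``groups`` is a list of collision groups (each a list of unit ids).
    """

    def __init__(self, message: str, groups: list | None = None):
        super().__init__(message)
        self.groups = groups or []


class RuleNotApplicableError(DepotError):
    """The unit does not match a rule's filter; no context path exists."""


class MissingAttributeError(DepotError):
    """A grouping attribute is absent and the rule's policy is ``fail``."""


class RuleConfigError(ValidationError):
    """A rule or project config file violates the schema.

    ``field_path`` points at the offending field, e.g. ``rules[1].grouping``.
    """

    def __init__(self, message: str, field_path: str | None = None):
        super().__init__(message)
        self.field_path = field_path


class ProjectionError(DepotError):
    """Target directory problems: owned by a different rule, unwritable..."""


class StaleCandidateError(DepotError):
    """Floating files changed (or vanished) since the candidate was scanned."""


class StoreIOError(DepotError):
    """Filesystem-level failure while touching the flat store."""
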