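"""Exception hierarchy for odnet.

Every error raised by the library derives from :class:`OdnetError` so callers
can catch library failures without masking programming errors.
"""


class OdnetError(Exception):
    """Base class for all odnet errors."""


class ParameterError(OdnetError, ValueError):
    """Invalid or infeasible parameter combination."""


class FormatError(OdnetError, ValueError):
    """Malformed input file (reaction table, Newick, config)."""


class AnnotationError(OdnetError):
    """A required node annotation (organism degree / membership) is missing."""


class MembershipError(OdnetError, KeyError):
    """An organism reaction set refers to a reaction outside the universe."""


class DegenerateNullError(OdnetError):
    """The reshuffling null has zero variance; no z-score can be formed."""


class StalledGrowthError(OdnetError):
    """Growth ran out of frontier neighbours before reaching the target size."""

    def __init__(self, achieved_size: int, target_size: int, achieved_set=frozenset()):
        self.achieved_size = achieved_size
        self.target_size = target_size
        self.achieved_set = frozenset(achieved_set)
        super().__init__(
            f"growth stalled at size {achieved_size} before reaching "
            f"target {target_size}: frontier exhausted"
        )


class FixtureLookupError(OdnetError, KeyError):
    """Unknown toy-fixture name."""


class ComparisonError(OdnetError):
    """Two reports cannot be compared (e.g. disjoint distance ranges)."""


class ConfigError(OdnetError, ValueError):
    """Invalid analysis configuration."""
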