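"""Exception hierarchy shared by all survflow stages.

Every error raised by the library derives from :class:`SurvFlowError`, so a
pipeline driver can distinguish input/schema problems (:class:`SchemaError`,
:class:`ParseError`) from statistical degeneracies (:class:`NoEventsError`,
:class:`DegenerateFeatureError`, ...) when mapping to exit codes.
"""


class SurvFlowError(Exception):
    """Base class for all survflow errors."""


class SchemaError(SurvFlowError):
    """A required column/feature is missing or mismatched."""


class ParseError(SurvFlowError):
    """A cell value could not be parsed into the required domain."""


class EmptyDatasetError(SurvFlowError):
    """No usable rows remain after reading/validation."""


class NoEventsError(SurvFlowError):
    """All subjects are censored; time-to-event estimation is undefined."""


class DegenerateFeatureError(SurvFlowError):
    """A feature is constant (no boundary / no information)."""


class EmptyGroupError(SurvFlowError):
    """A stratification rule produced an empty group."""


class GroupingError(SurvFlowError):
    """Group structure is missing or has fewer than two levels."""


class CollinearityError(SurvFlowError):
    """The observed information matrix is singular (dependent features)."""


class DegenerateScoreError(SurvFlowError):
    """All risk scores coincide; no threshold can split them."""


class NoPairsError(SurvFlowError):
    """No usable (comparable) pair exists for concordance."""


class FlatModelError(SurvFlowError):
    """All coefficients are zero; a nomogram scale cannot be defined."""


class DegenerateRangeError(SurvFlowError):
    """A feature's observed range has zero width."""
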