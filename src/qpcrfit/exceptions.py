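"""Exception hierarchy for qpcrfit."""


class QpcrFitError(Exception):
    """Base class for all qpcrfit errors."""


class SeriesFormatError(QpcrFitError):
    """Input table does not conform to the long-format schema."""


class SeriesParseError(QpcrFitError):
    """A cell could not be parsed as a number."""


class SeriesIntegrityError(QpcrFitError):
    """Schema is valid but the data are internally inconsistent."""


class NoGrowthZoneDataError(QpcrFitError):
    """No curve contributes any point inside the growth zone."""


class DegenerateDesignError(QpcrFitError):
    """Fit design is rank-deficient or has too few observations."""


class SingularGramError(QpcrFitError):
    """The Gram matrix L L^T of the difference transform is singular."""


class DisconnectedPairsError(QpcrFitError):
    """Difference rows do not span all points (pair graph disconnected)."""


class FlatCurveError(QpcrFitError):
    """Amplification curve shows no rise above baseline noise."""


class CqUndefinedError(QpcrFitError):
    """The requested Cq marker is undefined for this curve."""
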