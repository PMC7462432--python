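"""Named exceptions raised by the pipeline.

Every failure mode that a caller may want to handle separately gets its own
class; all inherit from :class:`AdherenetError` so blanket handling stays easy.
"""


class AdherenetError(Exception):
    """Base class for all package-specific errors."""


# --- io_formats ---------------------------------------------------------------

class ManifestError(AdherenetError):
    """Malformed cohort manifest (missing columns, empty, unreadable)."""


class MissingTimeseriesError(AdherenetError):
    """A time-series file referenced by the manifest does not exist."""


class RaggedMatrixError(AdherenetError):
    """A delimited matrix has rows of unequal length."""


class NonNumericCellError(AdherenetError):
    """A matrix cell could not be parsed as a number (message names row/column)."""


class RoiCountMismatchError(AdherenetError):
    """Participants' time-series files disagree on the number of ROIs."""


class DuplicateParticipantError(AdherenetError):
    """The same participant id appears more than once in a manifest."""


class AffiliationCoverageError(AdherenetError):
    """An ROI has no network affiliation (message names the ROI)."""


class UnknownRoiError(AdherenetError):
    """The affiliation table names an ROI absent from the time series."""


class NetworkCountError(AdherenetError):
    """Strict mode: the affiliation table does not define exactly 5 networks."""


class ConfigError(AdherenetError):
    """Invalid run configuration (bad threshold grid, fractions, counts)."""


# --- connectome ---------------------------------------------------------------

class ZeroVarianceError(AdherenetError):
    """An ROI time series is constant, so Pearson r is undefined for it."""


class UndefinedCorrelationError(AdherenetError):
    """Fewer than 3 timepoints: sample correlation is degenerate."""


# --- graph_metrics ------------------------------------------------------------

class UndefinedSegregationError(AdherenetError):
    """Within-network density is 0, so system segregation has a 0 denominator."""


class SingletonSubnetworkError(AdherenetError):
    """A subnetwork has fewer than 2 nodes: no within-network pairs exist."""


# --- synthetic_cohort ---------------------------------------------------------

class DegenerateParamsError(AdherenetError):
    """Simulation parameters that yield collinear or unusable cohorts."""


# --- stat_inference -----------------------------------------------------------

class ConstantVectorError(AdherenetError):
    """Permutation correlation requested on a constant vector."""
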