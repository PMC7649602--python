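"""Exception hierarchy for thoipakit."""


class ThoipaKitError(Exception):
    """Base class for all thoipakit errors."""


class InvalidSignalError(ThoipaKitError):
    """A dimerisation signal violates its constraints (e.g. wildtype w <= 0)."""


class EmptyDataError(ThoipaKitError):
    """An operation received no usable data."""


class EmptyStructureError(ThoipaKitError):
    """A structure or chain contains no heavy atoms."""


class OrientationError(ThoipaKitError):
    """Relative helix orientation could not be determined."""


class ConfigurationError(ThoipaKitError):
    """Invalid or inconsistent configuration (missing chain, missing scale entry...)."""


class SchemaError(ThoipaKitError):
    """A feature table does not match the expected census/schema."""


class InsufficientDepthError(ThoipaKitError):
    """The alignment has too few valid rows for the requested computation."""


class InsufficientLengthError(ThoipaKitError):
    """The TMD is too short for the requested computation."""


class NumericConditioningError(ThoipaKitError):
    """A covariance matrix is singular; raise the pseudocount weight."""


class DegenerateLabelError(ThoipaKitError):
    """Training labels contain a single class."""


class UndefinedMetricError(ThoipaKitError):
    """A metric is undefined for the given inputs (single-class labels, empty truth...)."""


class NotADimerError(ThoipaKitError):
    """A structure expected to contain two chains does not."""


class SpecError(ThoipaKitError):
    """A fixture specification is internally inconsistent."""
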