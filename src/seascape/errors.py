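"""Exception hierarchy for the seascape package."""


class SeascapeError(Exception):
    """Base class for all seascape errors."""


class RectangleCodeError(SeascapeError, ValueError):
    """Malformed or out-of-grid ICES statistical rectangle code."""


class DegenerateFitError(SeascapeError, ValueError):
    """Length-weight regression is undefined (e.g. all lengths identical)."""


class DegenerateSpatialError(SeascapeError, ValueError):
    """A spatial statistic is undefined for this map.

    Raised when all values are equal (no above-median subset, zero-variance
    Moran's I), all points are coincident (zero maximum distance), or all
    centre-of-gravity weights are zero.
    """


class InsufficientDataError(SeascapeError, ValueError):
    """Too few observations or too little series overlap for the statistic."""


class ValidationError(SeascapeError, ValueError):
    """An input table failed schema validation."""
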