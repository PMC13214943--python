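"""Exception hierarchy shared across the pipeline stages."""


class GeopharmError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(GeopharmError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateGeometryError(InvalidInputError):
    """Fewer than three points, or all points collinear: no triangulation exists."""


class SchemaError(GeopharmError, KeyError):
    """A required column or feature is missing, or feature sets disagree."""


class JoinError(GeopharmError, KeyError):
    """A table references keys absent from the table it is joined against."""


class InvalidConfigError(GeopharmError, ValueError):
    """A configuration file or mapping fails validation."""


class EmptyZoneError(GeopharmError, ValueError):
    """A bounding box contains no raster cell centers."""


class EmptyOutputError(GeopharmError, ValueError):
    """A join or filter left zero rows."""


class DependencyError(GeopharmError, FileNotFoundError):
    """A pipeline stage was requested before its upstream artefacts exist."""


class UndefinedR2Error(GeopharmError, ArithmeticError):
    """R^2 is undefined because the evaluation target has zero variance.

    RMSE and MAE are still well defined and are carried on the exception.
    """

    def __init__(self, msg: str, rmse: float, mae: float, n: int):
        super().__init__(msg)
        self.rmse = rmse
        self.mae = mae
        self.n = n
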