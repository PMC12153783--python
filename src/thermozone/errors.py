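"""Package-specific exceptions."""


class ThermozoneError(Exception):
    """Base class for all thermozone errors."""


class InvalidInputError(ThermozoneError, ValueError):
    """An input value violates a documented precondition."""


class UnfittableSeriesError(ThermozoneError, ValueError):
    """A precipitation series cannot support a gamma fit
    (too few positive values, or zero sample variance)."""


class DegenerateGeometryError(ThermozoneError, ValueError):
    """All sample locations coincide; no spatial structure can be estimated."""


class SingularKrigingSystemError(ThermozoneError):
    """The ordinary-kriging system is singular.

    Usually caused by duplicated sample locations combined with a zero
    nugget; deduplicate the samples or add a small nugget.
    """


class NoSpatialStructureWarning(UserWarning):
    """The empirical semivariogram is flat; the fitted model is (near) pure nugget."""
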