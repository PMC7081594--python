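"""Exception hierarchy for mycometry.

All package errors derive from :class:`MycometryError` so callers can catch
one base class; each subclass also derives from the closest builtin so that
idiomatic ``except ValueError`` / ``except KeyError`` code keeps working.
"""


class MycometryError(Exception):
    """Base class for all mycometry errors."""


class ValidationError(MycometryError, ValueError):
    """A configuration or input value violates its documented contract."""


class InsufficientDataError(MycometryError, ValueError):
    """Not enough observations to perform the requested computation."""


class ContaminatedPlateError(MycometryError, ValueError):
    """A contamination-flagged plate was passed to a fitting routine."""


class DomainError(MycometryError, ValueError):
    """A value is outside the mathematical domain of the statistic."""


class DegenerateDataError(MycometryError, ValueError):
    """Zero-variance or otherwise degenerate input to a statistical test."""


class MissingReferenceError(MycometryError, KeyError):
    """A lab has no usable reference-group plates for REU normalization."""

    def __init__(self, labs, reference):
        self.labs = list(labs)
        self.reference = reference
        super().__init__(
            f"labs {self.labs} have no non-contaminated reference plates "
            f"for reference {reference}"
        )

    def __str__(self) -> str:  # KeyError would repr() the message otherwise
        return self.args[0]


class GeometryError(MycometryError, ValueError):
    """Plate/image geometry is inconsistent (radius beyond dish, ray exits frame...)."""


class DishDetectionError(MycometryError, RuntimeError):
    """Automatic dish-rim detection failed; calibrate manually."""


class ExtractionError(MycometryError, RuntimeError):
    """No measurement axis yielded any trace crossing."""


class SchemaError(MycometryError, ValueError):
    """A trace CSV file violates the required schema."""
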