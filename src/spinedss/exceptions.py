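"""Typed errors shared across the pipeline.

Every failure mode a caller may want to branch on gets its own class; all
inherit from :class:`SpineDSSError` so a CLI can catch one type and map it
to a nonzero exit code.
"""


class SpineDSSError(Exception):
    """Base class for all spinedss errors."""

    #: machine-parsable code used by the CLI
    code = "error"


class ValidationError(SpineDSSError):
    """An input object violates its documented invariants."""

    code = "validation"


class GenerationError(SpineDSSError):
    """The phantom generator could not satisfy a requested target."""

    code = "generation"


class ChainTooShortError(SpineDSSError):
    """Fewer vertebra candidates than the minimum needed for a chain."""

    code = "chain_too_short"


class DegenerateGeometryError(SpineDSSError):
    """Coincident points or zero-length segments make a quantity undefined."""

    code = "degenerate_geometry"


class UnrepairableChainError(SpineDSSError):
    """No trusted reference points remain to anchor a chain repair."""

    code = "unrepairable_chain"


class GeometryError(SpineDSSError):
    """A requested crop or region lies outside the image."""

    code = "geometry"


class EmptyMaskError(SpineDSSError):
    """An operation requiring a nonempty mask received an empty one."""

    code = "empty_mask"


class UndefinedMetricError(SpineDSSError):
    """A ratio metric's denominator is zero; refusing to return a silent 0."""

    code = "undefined_metric"


class TrainingError(SpineDSSError):
    """Training data does not support the requested model (e.g. missing class)."""

    code = "training"


class NotTrainedError(SpineDSSError):
    """Prediction was requested from a model that has not been trained."""

    code = "not_trained"


class UnitError(SpineDSSError):
    """A physical-unit conversion was requested without the needed spacing."""

    code = "unit"
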