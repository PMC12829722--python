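"""Exception hierarchy for the EUS elastography quantification pipeline.

Every QC rejection is an exception type of its own so callers (and the CLI)
can log the reason instead of receiving a fabricated elasticity value.
"""


class EuseiError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(EuseiError, ValueError):
    """A precondition on an argument was violated."""


class GeometryError(EuseiError):
    """Panel split / mask geometry inconsistency."""


class IndeterminateColorError(EuseiError):
    """Mean color is (near-)achromatic: hue is meaningless, no projection.

    QC flag name: ``achromatic``.
    """

    flag = "achromatic"


class DegenerateLesionError(EuseiError):
    """Mask empty after filtering; nothing to quantify."""

    flag = "degenerate-lesion"


class LowColorCoverageError(EuseiError):
    """Too few colored pixels inside the solid lesion to trust the average.

    QC flag name: ``low-color-fraction``.
    """

    flag = "low-color-fraction"


class CalibrationError(EuseiError):
    """Quantile targets infeasible for the phantom distribution family."""


class SeparationError(EuseiError):
    """Complete separation in a logistic fit; names the covariate."""

    def __init__(self, covariate: str):
        self.covariate = covariate
        super().__init__(f"complete separation on covariate {covariate!r}")


class UngroupableError(EuseiError):
    """NIH risk category unknown; patient cannot be assigned a binary group."""
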