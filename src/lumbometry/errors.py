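"""Exception hierarchy shared across the pipeline.

Every failure mode that aborts a measurement maps to one of these types so the
CLI can translate them into stable exit codes (usage = 1, data/anatomy = 2).
"""


class LumbometryError(Exception):
    """Base class for all package errors."""


class MissingKeypointError(LumbometryError):
    """A required landmark is absent from a KeyPointSet."""

    def __init__(self, name: str):
        self.name = name
        super().__init__(f"required landmark {name!r} is missing")


class DegenerateGeometryError(LumbometryError):
    """Coincident points, parallel lines, or a zero-length reference span."""


class InfeasibleSpecError(LumbometryError):
    """Phantom spec cannot be realised inside the requested frame."""


class AnatomyCountError(LumbometryError):
    """Connected-region census does not match 5 lumbar bodies + 1 sacrum."""


class CornerShortageError(LumbometryError):
    """Too few Harris corner candidates survived for a region."""

    def __init__(self, identity: str, found: int, needed: int):
        self.identity = identity
        self.found = found
        self.needed = needed
        super().__init__(
            f"region {identity}: found {found} corner candidates, need {needed}"
        )


class LabelingError(LumbometryError):
    """Corner candidates cannot be split into superior/inferior pairs."""


class DataError(LumbometryError):
    """Malformed or inconsistent input data (files, shapes, spacings)."""


class ConfigurationError(LumbometryError):
    """Inconsistent network or run configuration."""


class TrainingError(LumbometryError):
    """Non-finite loss or other unrecoverable training failure."""

    def __init__(self, message: str, epoch: int | None = None):
        self.epoch = epoch
        super().__init__(message if epoch is None else f"{message} (epoch {epoch})")


class UndefinedStatisticError(LumbometryError):
    """A statistic is undefined for the given data (e.g. zero variance)."""
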