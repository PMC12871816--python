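"""Exception hierarchy.

All package errors derive from :class:`TailgateError` so callers can catch
one base class; subclasses distinguish I/O, geometry, simulation and
estimation failures.
"""


class TailgateError(Exception):
    """Base class for all package errors."""


class ValidationError(TailgateError):
    """An object violates one of its documented invariants."""


class PDBParseError(TailgateError):
    """Malformed fixed-column PDB input; message names the line number."""


class TrajectoryFormatError(TailgateError):
    """Trajectory container does not start with the expected magic string."""


class TrajectoryCorruptionError(TailgateError):
    """Trajectory payload truncated or inconsistent with its header."""


class GeometryError(TailgateError):
    """Synthetic system parameters describe an unrealisable geometry."""


class DivergedError(TailgateError):
    """Integration produced non-finite coordinates."""

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step


class CalibrationError(TailgateError):
    """No swept tail radius reached the target dwell-ratio band."""

    def __init__(self, message: str, table=None):
        super().__init__(message)
        self.table = table


class EstimationError(TailgateError):
    """A statistic cannot be estimated from the given samples."""
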