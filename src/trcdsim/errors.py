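"""Exception hierarchy.

All trcdsim-specific failures derive from :class:`TRCDSimError`, and each also
inherits the closest built-in so that generic ``except ValueError`` style
handling keeps working.
"""


class TRCDSimError(Exception):
    """Base class for all trcdsim errors."""


class ParameterError(TRCDSimError, ValueError):
    """An invalid numeric parameter (e.g. non-positive line width)."""


class DimensionError(TRCDSimError, ValueError):
    """An array argument has the wrong shape (e.g. a non-3-vector dipole)."""


class GridMismatchError(TRCDSimError, ValueError):
    """Two spectra that must share a wavelength grid do not."""


class EmptyInputError(TRCDSimError, ValueError):
    """An operation that needs at least one element received none."""


class GeometryError(TRCDSimError, ValueError):
    """Degenerate geometry (coincident or collinear points) in a torsion."""


class SampleSizeError(TRCDSimError, ValueError):
    """Too few samples/trajectories for a statistical estimator."""


class EmptyWindowError(TRCDSimError, ValueError):
    """A time window selects no rows/frames."""


class TrajectoryParseError(TRCDSimError, ValueError):
    """A trajectory table violates the format contract.

    Carries a 1-based ``line`` number when the offending row is known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class XYZParseError(TRCDSimError, ValueError):
    """A multi-frame XYZ file or an atom-index quadruple is invalid."""


class IntegratorError(TRCDSimError, RuntimeError):
    """The surface-hopping integrator lost accuracy (norm drift too large)."""
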