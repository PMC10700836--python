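"""Exception taxonomy shared across the pipeline stages."""


class AcclimateError(Exception):
    """Base class for all package-specific failures."""


class MissingDataError(AcclimateError):
    """No usable station data for an interpolation target."""


class CoverageError(AcclimateError):
    """A historical reference window reaches outside the weather record."""


class ExposureMissingError(CoverageError):
    """An exposure window is not fully covered by a county daily series."""


class ConvergenceError(AcclimateError):
    """Alternating demeaning failed to converge within the iteration cap."""


class CollinearityError(AcclimateError):
    """Design matrix is rank deficient after the within transformation."""

    def __init__(self, columns, message=None):
        self.columns = list(columns)
        super().__init__(message or f"collinear columns: {self.columns}")


class AlignmentError(AcclimateError):
    """Two tables that must share an index do not."""
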