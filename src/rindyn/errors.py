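"""Exception hierarchy used across the package."""


class RindynError(Exception):
    """Base class for all package-specific errors."""


class PDBParseError(RindynError):
    """A structure file could not be parsed (carries file/line context)."""


class FormatError(RindynError):
    """Structurally inconsistent input, e.g. models with differing atom counts."""


class SelectionError(RindynError):
    """Invalid atom-selection expression; message names the offending token."""


class SpecError(RindynError):
    """Invalid synthetic-data specification (e.g. non-PSD covariance)."""


class SuperpositionError(RindynError):
    """Degenerate superposition problem (< 3 atoms or collinear geometry)."""


class AnalysisError(RindynError):
    """Invalid analysis request (empty selection, too few frames, ...)."""


class FitError(RindynError):
    """Non-linear fit failed to converge; ``best_params`` holds the last iterate."""

    def __init__(self, message, best_params=None):
        super().__init__(message)
        self.best_params = best_params
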