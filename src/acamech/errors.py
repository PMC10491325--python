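"""Exception hierarchy shared across the analysis modules."""


class AcamechError(Exception):
    """Base class for all package errors."""


class InvalidGeometryError(AcamechError):
    """Reference geometry violates 0 < Ri < Ro or L > 0."""


class InfeasibleGeometryError(AcamechError):
    """Deformed state incompatible with incompressibility (negative radicand)."""


class DegenerateWallError(AcamechError):
    """Wall thickness is zero; stresses are undefined."""


class NormalizationAnchorError(AcamechError):
    """No zero-pressure point available to anchor stretch normalization."""


class FitError(AcamechError):
    """Nonlinear fit failed to converge or input is degenerate."""


class ExtrapolationError(AcamechError):
    """Requested pressure lies outside the recorded range."""


class ParseError(AcamechError):
    """Malformed input file; message names the offending row/column."""
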