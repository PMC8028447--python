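"""Exception hierarchy for the OJIP/canopy analysis pipeline."""


class OjipError(Exception):
    """Base class for all package-specific errors."""


class FormatError(OjipError):
    """A delimited input file is structurally malformed (e.g. missing columns)."""


class ValidationError(OjipError):
    """Input data violates a documented invariant (non-monotone time, negative
    fluorescence, inconsistent metadata, invalid category labels, ...)."""


class OutOfRangeError(OjipError):
    """A query time falls outside the recorded range of a transient."""


class DegenerateTransientError(OjipError):
    """The transient carries no variable fluorescence (FM <= F0), so the
    JIP-test parameters are undefined."""


class UndefinedParameterError(OjipError):
    """A derived parameter is undefined for these landmarks (VJ in {0, 1} or
    phi_Po = 0)."""


class AssayInconsistencyError(OjipError):
    """Absorbance readings yield a negative pigment concentration, signalling
    swapped wavelengths or a blank failure."""


class ParameterError(OjipError):
    """Invalid simulation or configuration parameters."""
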