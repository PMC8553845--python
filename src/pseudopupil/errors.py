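"""Exception hierarchy for the pseudopupil pipeline."""


class PseudopupilError(Exception):
    """Base class for all package errors."""


class InvalidInputError(PseudopupilError, ValueError):
    """Non-finite or otherwise malformed numeric input."""


class ConfigurationError(PseudopupilError, ValueError):
    """Inconsistent configuration (degenerate image size, zero pitch, ...)."""


class PoseOutOfRangeError(PseudopupilError, ValueError):
    """Goniometer pose falls outside the gaze range covered by the eye model."""


class NoSignalError(PseudopupilError, ValueError):
    """Flat frame or flat profile: there is no peak to locate."""


class UnboundedProfileError(PseudopupilError, ValueError):
    """Intensity profile does not cross half-maximum on both sides of the peak."""


class RegistrationError(PseudopupilError, ValueError):
    """Landmark set insufficient or degenerate for solving the lattice frame."""


class DegenerateNodeError(PseudopupilError, ValueError):
    """Displacement matrix is (near-)singular; the map node cannot be inverted."""


class MapInputError(PseudopupilError, ValueError):
    """Observations do not form the rectangular goniometer grid a map requires."""


class ParseError(PseudopupilError, ValueError):
    """Text-file parse failure; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
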