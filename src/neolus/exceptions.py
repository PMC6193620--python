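"""Exception hierarchy shared across the pipeline."""


class NeolusError(Exception):
    """Base class for all package-specific errors."""


class FormatError(NeolusError):
    """An input file is not in a supported format (compressed DICOM, RGB image...)."""


class ValidationError(NeolusError):
    """Tabular or record-level input violates the study schema."""


class CapacityError(NeolusError):
    """The frame cannot hold a region of interest of the requested area."""

    def __init__(self, message: str, max_area: int):
        super().__init__(message)
        self.max_area = max_area


class DegenerateGLCMError(NeolusError):
    """No valid pixel pair exists for the requested co-occurrence offset."""
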