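"""Exception hierarchy shared across the pipeline."""


class FsmiError(Exception):
    """Base class for all package-specific errors."""


class ChipValidationError(FsmiError, ValueError):
    """A chip definition violates an invariant (duplicate IDs, empty panel, ...)."""


class FormatError(FsmiError, ValueError):
    """A file does not conform to the expected tabular dialect."""


class SpotTableParseError(FormatError):
    """A spot-table row could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class LayoutCapacityError(FsmiError, ValueError):
    """The requested field geometry cannot hold antibodies x replicates + controls."""


class PairingError(FsmiError, ValueError):
    """Sample and blank assays do not share a layout / chip."""


class BaselineError(FsmiError, RuntimeError):
    """No valid control spot is available; the assay cannot be quantified."""


class AnnotationError(FsmiError, KeyError):
    """A positive call falls in a group with no antibodies annotated on the chip."""


class DuplicateAssayError(FsmiError, ValueError):
    """Two checkerboard assays claim the same antigen."""


class NoOptimumError(FsmiError, RuntimeError):
    """All dilution-series signals are non-positive; no working dilution exists."""


class ExtrapolationError(FsmiError, ValueError):
    """A calibration curve was queried outside the tested concentration range."""
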