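"""Exception hierarchy shared across the package."""


class ErPathwayError(Exception):
    """Base class for package errors."""


class ConfigurationError(ErPathwayError, ValueError):
    """Inconsistent or incomplete configuration (empty model, platform
    mismatch, evidence for unknown genes, zero gene overlap...)."""


class UninformativeModelError(ErPathwayError, ValueError):
    """The model cannot discriminate active from inactive: every gene is
    uninformative, or the score range collapses to a point."""


class CalibrationError(ErPathwayError, RuntimeError):
    """Calibration failed (no gene passed selection, classes too small,
    scores do not separate the ground-truth classes).

    Carries the gene-selection report, when available, in ``report``.
    """

    def __init__(self, message, report=None):
        super().__init__(message)
        self.report = report


class ParseError(ErPathwayError, ValueError):
    """Malformed input file; ``line`` is the 1-based offending line."""

    def __init__(self, message, line=None):
        super().__init__(message)
        self.line = line
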