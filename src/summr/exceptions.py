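"""Exception hierarchy for summr.

Every error raised by the library derives from :class:`SummrError`, so callers
can catch one type at a pipeline boundary. Row- and SNP-level problems carry
machine-readable ``reason`` codes that also appear in run logs.
"""


class SummrError(Exception):
    """Base class for all summr errors."""


class ConfigError(SummrError):
    """A configuration problem: missing column, missing file, bad threshold."""


class FormatError(SummrError):
    """A malformed input file (non-square LD table, |r| > 1, asymmetry...)."""


class RowError(SummrError):
    """A single unusable data row.

    Parameters
    ----------
    line : int
        1-based line number in the source file (header included in the count).
    reason : str
        Machine-readable reason code, e.g. ``"nonpositive_se"``.
    """

    def __init__(self, line: int, reason: str, detail: str = ""):
        self.line = line
        self.reason = reason
        msg = f"line {line}: {reason}"
        if detail:
            msg += f" ({detail})"
        super().__init__(msg)


class EmptyInstrumentSetError(SummrError):
    """Harmonization or selection retained zero SNPs."""


class InsufficientInstrumentsError(SummrError):
    """An estimator requires more SNPs than were supplied."""


class DegenerateInstrumentError(SummrError):
    """All SNP-exposure effects are zero; the causal slope is unidentified."""


class UndefinedRatioError(SummrError):
    """Wald ratio requested for a SNP with zero exposure effect."""


class NumericalError(SummrError):
    """A matrix that must be positive definite is not, or similar."""


class GenerationError(SummrError):
    """The requested synthetic-data configuration is infeasible."""
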