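"""Exception hierarchy for tsscan."""


class TsScanError(Exception):
    """Base class for all tsscan errors."""


class InputError(TsScanError):
    """A required input file is missing, unindexed, or malformed."""


class ContigError(TsScanError):
    """A requested contig is absent from the BAM header or reference."""


class ParseError(TsScanError):
    """A region or annotation file could not be parsed.

    Carries the 1-based line number of the offending line when known.
    """

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class ValidationError(TsScanError):
    """Input content violates a contract (unknown TsType, unpaired lists...)."""
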