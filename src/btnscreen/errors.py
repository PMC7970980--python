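"""Exception hierarchy for the screening pipeline."""


class BTNScreenError(Exception):
    """Base class for all package errors."""


class ParameterError(BTNScreenError, ValueError):
    """An operation was called with an out-of-range parameter."""


class AlignmentError(BTNScreenError, ValueError):
    """Sequences that must share an alignment have incompatible lengths."""


class InputError(BTNScreenError, ValueError):
    """Malformed or empty input data."""


class DiagnosisError(BTNScreenError):
    """A ploidy diagnosis could not be made (e.g. no diploid anchor peak)."""


class NoAlleleError(BTNScreenError):
    """Every colony in a cloning experiment was excluded as an artifact."""


class UnresolvableMixtureError(BTNScreenError):
    """Too many mixed chromatogram sites for a major/minor decomposition."""


class FastaFormatError(BTNScreenError, ValueError):
    """A FASTA file violated the expected format; offending records listed."""

    def __init__(self, message: str, records: list | None = None):
        super().__init__(message)
        self.records = records or []


class PackagingError(BTNScreenError):
    """A bundled data file is missing or corrupted."""


class ConfigurationError(BTNScreenError, ValueError):
    """A pipeline or panel configuration is invalid or incomplete."""
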