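"""Exception hierarchy shared across the toolkit."""


class EvcfKitError(Exception):
    """Base class for all evcfkit errors."""


class VcfParseError(EvcfKitError):
    """A line could not be parsed as VCF; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class InvalidRecordError(VcfParseError):
    """A record parsed but violates an invariant (e.g. END < POS)."""


class RecordOrderError(EvcfKitError):
    """Records are not sorted by contig (header order) then position."""


class SerializationError(EvcfKitError):
    """A record cannot be serialized (undeclared INFO key, missing metadata)."""


class ArrayReportError(EvcfKitError):
    """A genotyping-array report row is malformed."""


class CatalogError(EvcfKitError):
    """A site catalog is inconsistent (bad frequencies, missing alleles)."""


class OverlapError(EvcfKitError):
    """Two gVCF records overlap where the format forbids it."""


class RegionCoverageError(EvcfKitError):
    """A requested region lies outside every available coverage profile."""
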