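"""Exception hierarchy for the spikegbs package.

All errors derive from :class:`SpikeGBSError`; most are also ``ValueError``
subclasses so that generic callers can catch them without importing this
module.
"""


class SpikeGBSError(Exception):
    """Base class for all spikegbs errors."""


class AlphabetError(SpikeGBSError, ValueError):
    """A sequence contains characters outside the {A, C, G, T} alphabet."""


class LengthError(SpikeGBSError, ValueError):
    """A sequence has the wrong length (e.g. a barcode of unexpected size)."""


class ValidationError(SpikeGBSError, ValueError):
    """A domain object violates one of its invariants."""


class ConversionError(SpikeGBSError, ValueError):
    """A KASP primer pair cannot be converted to a common forward primer."""


class AmbiguityError(SpikeGBSError, ValueError):
    """An assembled construct cannot be parsed unambiguously."""


class CapacityError(SpikeGBSError, ValueError):
    """A barcode set of the requested size/distance cannot be generated."""


class MarkerDefinitionError(SpikeGBSError, ValueError):
    """A marker definition is internally inconsistent."""


class ConfigError(SpikeGBSError, ValueError):
    """A run or simulation configuration is invalid."""


class LabelingError(SpikeGBSError, ValueError):
    """Cluster centroids cannot be injectively mapped to genotype classes."""


class FastqParseError(SpikeGBSError, ValueError):
    """A FASTQ record could not be parsed; carries the record index."""

    def __init__(self, record_index: int, message: str = ""):
        self.record_index = record_index
        detail = f": {message}" if message else ""
        super().__init__(f"unreadable FASTQ record at index {record_index}{detail}")


class InputError(SpikeGBSError, ValueError):
    """Two inputs that must share a domain (samples x loci) do not."""


class PipelineError(SpikeGBSError, RuntimeError):
    """A pipeline stage failed."""
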