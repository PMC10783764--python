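"""Typed errors raised by the pipeline stages."""


class AntiSDScanError(Exception):
    """Base class for all package errors."""


class FastaError(AntiSDScanError):
    """Malformed FASTA input (empty file, duplicate ids, illegal characters)."""


class GeneTableError(AntiSDScanError):
    """Malformed gene annotation (missing strand, out-of-bounds coordinate)."""


class ParameterTableError(AntiSDScanError):
    """Malformed nearest-neighbor parameter file."""


class CoreUnresolvableError(AntiSDScanError):
    """Pairwise alignment placed the reference central U in a gap."""


class SimulationError(AntiSDScanError):
    """Synthetic-genome generation failed (e.g. rejection-sampling cap hit)."""


class PipelineError(AntiSDScanError):
    """A pipeline stage aborted; message carries the stage name and record id."""
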