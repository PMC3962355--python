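"""Exception hierarchy shared across the pipeline."""


class CoralmirError(Exception):
    """Base class for all pipeline errors."""


class FormatError(CoralmirError, ValueError):
    """Malformed on-disk input (FASTA/FASTQ/OBO/TSV)."""


class CycleError(FormatError):
    """The ontology's is_a graph contains a cycle."""


class ConfigError(CoralmirError, ValueError):
    """Invalid parameter or configuration value."""


class DegenerateCandidateError(CoralmirError):
    """A precursor candidate whose mature arm forms no duplex at all."""
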