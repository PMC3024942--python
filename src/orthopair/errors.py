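"""Exception hierarchy shared by all orthopair modules."""


class OrthoPairError(Exception):
    """Base class for every error raised by this package."""


class BlastParseError(OrthoPairError):
    """Malformed BLAST tabular input (wrong column count, bad number)."""


class FastaError(OrthoPairError):
    """Malformed proteome FASTA (duplicate accession, empty sequence...)."""


class ManifestError(OrthoPairError):
    """Malformed organism manifest (duplicate id, missing field)."""


class ConfigurationError(OrthoPairError):
    """Inconsistent user-supplied parameters (e.g. min_len > max_len)."""


class UnknownAccessionError(OrthoPairError):
    """A hit or query references a protein accession that is not known."""


class UnknownOrganismError(OrthoPairError):
    """An operation references an organism absent from the dataset."""


class ExportError(OrthoPairError):
    """Unsupported (what, format) export combination."""


class OracleSizeError(OrthoPairError):
    """The brute-force oracle was handed an instance above its size guard."""
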