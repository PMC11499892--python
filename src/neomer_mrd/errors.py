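"""Exception hierarchy."""


class NeomerMRDError(Exception):
    """Base class for package errors."""


class ConfigError(NeomerMRDError, ValueError):
    """Invalid configuration value or combination."""


class DataIntegrityError(NeomerMRDError, ValueError):
    """Input data contradicts itself (e.g. variant ref != reference base)."""


class FastqParseError(NeomerMRDError, ValueError):
    """Malformed FASTQ record; message names the record number."""


class UnfittableError(NeomerMRDError, ValueError):
    """A model cannot be fitted (e.g. no comparable survival pairs)."""
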