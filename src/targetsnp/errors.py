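"""Exception types shared across the toolkit."""


class TargetSnpError(Exception):
    """Base class for all toolkit errors."""


class DegenerateLocusError(TargetSnpError):
    """A locus has no usable (non-missing) genotype data."""


class MissingSequenceError(TargetSnpError):
    """A requested chromosome/contig is absent from the reference."""


class ConfigError(TargetSnpError):
    """Invalid parameter combination or malformed run configuration."""
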