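"""Exception hierarchy."""


class ModuleDiseaseError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ModuleDiseaseError, ValueError):
    """Invalid simulation or pipeline configuration."""


class DegenerateSampleError(ModuleDiseaseError, ValueError):
    """A sample column has zero variance and cannot be z-scored."""


class GmtFormatError(ModuleDiseaseError, ValueError):
    """Malformed GMT gene-set file."""
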