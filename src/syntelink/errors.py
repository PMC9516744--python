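"""Exception hierarchy shared across the package."""


class SynteLinkError(Exception):
    """Base class for all package errors."""


class AnnotationError(SynteLinkError):
    """Malformed or inconsistent genome annotation input."""


class IdMappingError(AnnotationError):
    """FASTA record IDs could not be resolved to annotated gene IDs."""


class TranslationError(SynteLinkError):
    """A CDS does not translate to its declared protein."""


class DistanceUndefinedError(SynteLinkError):
    """Gene-order distance requested between genes on different chromosomes."""


class FamilyError(SynteLinkError):
    """Problem with a seed panel or family label."""


class ConfigError(SynteLinkError):
    """Invalid run or simulation configuration."""
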