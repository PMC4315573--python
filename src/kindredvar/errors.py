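"""Exception hierarchy shared across the package."""


class KindredVarError(Exception):
    """Base class for all package-specific errors."""


class VcfFormatError(KindredVarError):
    """A VCF file could not be parsed."""


class PedigreeError(KindredVarError):
    """A pedigree file violates the nuclear-family constraints."""


class ConfigurationError(KindredVarError):
    """Inconsistent or impossible configuration (exit code 2 in the CLI)."""


class DataError(KindredVarError):
    """A data value is out of its legal domain (e.g. allele frequency > 1)."""


class ReferenceMismatchError(KindredVarError):
    """A variant's REF allele disagrees with the reference/CDS sequence."""


class TranslationError(KindredVarError):
    """A coding sequence contains bases outside {A, C, G, T}."""


class HgvsParseError(KindredVarError, ValueError):
    """A protein-level HGVS string does not match the supported grammar."""


class AnnotationWarning(UserWarning):
    """Non-fatal problem in transcript annotation (e.g. CDS not divisible by 3)."""
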