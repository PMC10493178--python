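"""Exception hierarchy.

``ConfigError`` maps to CLI exit status 2, everything else derived from
``VcfCohortError`` to exit status 1.
"""


class VcfCohortError(Exception):
    """Base class for all package errors."""


class FormatError(VcfCohortError):
    """Malformed input file (bad VCF/GTF/GFF3/BED/TSV content)."""


class InvalidVariantError(VcfCohortError):
    """Allele pair that cannot represent a variant (e.g. ref == alt)."""


class ConfigError(VcfCohortError):
    """Invalid run configuration (bad manifest, bins, ranks, paths...)."""


class DegenerateInputError(VcfCohortError):
    """Structurally valid input on which the operation is undefined."""


class GenerationError(VcfCohortError):
    """Infeasible synthetic-fixture specification (e.g. pool exhausted)."""
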