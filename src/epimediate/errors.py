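"""Exception hierarchy shared across the package."""


class EpimediateError(Exception):
    """Base class for all package-specific errors."""


class FormatError(EpimediateError):
    """A file does not conform to the expected tabular dialect."""


class ValidationError(EpimediateError, ValueError):
    """Parsed data violate a structural or range invariant."""


class DegenerateInstrumentError(EpimediateError):
    """The genetic instrument carries no usable variation (constant dosage,
    zero genotype-exposure coefficient)."""


class HarmonizationError(EpimediateError):
    """Effect alleles of two summary statistics cannot be reconciled."""


class ChainingError(EpimediateError):
    """Two IV estimates do not share the intermediate trait and cannot be
    multiplied into a mediated effect."""
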