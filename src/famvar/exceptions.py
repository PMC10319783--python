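"""Exception hierarchy shared by all famvar modules."""


class FamvarError(Exception):
    """Base class for every error raised by famvar."""


class ParseError(FamvarError):
    """A text input (PED/TSV/GMT) could not be parsed."""


class FormatError(FamvarError):
    """A structured file (VCF) violates its format contract."""


class ValidationError(FamvarError):
    """Parsed data violates a domain invariant."""


class ConsistencyError(FamvarError):
    """Two inputs that must agree (samples vs pedigree, candidates vs universe) do not."""


class ConfigurationError(FamvarError):
    """A configuration value or pattern is invalid."""
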