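"""Exception types shared across the package."""


class CoevonetError(Exception):
    """Base class for all package errors."""


class FormatError(CoevonetError, ValueError):
    """Malformed input file (bad Newick syntax, non-binary matrix cell, ...)."""


class ValidationError(CoevonetError, ValueError):
    """Structurally valid input that violates a semantic contract."""
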