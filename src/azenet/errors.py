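"""Exception hierarchy shared across the package.

``ValidationError`` maps to CLI exit code 2, every other ``AzenetError``
to exit code 3.
"""


class AzenetError(Exception):
    """Base class for all package errors."""


class ValidationError(AzenetError, ValueError):
    """Invalid inputs: bad parameters, malformed tables, mismatched ids."""


class DegenerateInputError(AzenetError, ValueError):
    """Structurally valid input on which the operation is undefined
    (e.g. an all-zero sample, a group of size one)."""
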