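"""Exception hierarchy.

Three families, mirroring the three ways a call can go wrong:
configuration (bad parameter values), data (inputs that violate the
data contract), and contract (caller passed structurally incompatible
arguments, e.g. mismatched shapes).
"""


class HarfuseError(Exception):
    """Base class for all package errors."""


class ConfigurationError(HarfuseError, ValueError):
    """A parameter or config key has an invalid value; message names it."""


class DataError(HarfuseError, ValueError):
    """Input data violates a precondition (e.g. an all-missing channel)."""


class ContractError(HarfuseError, ValueError):
    """Arguments are mutually inconsistent (shape/label/column mismatch)."""
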