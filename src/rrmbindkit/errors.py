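"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: input/validation problems exit 2,
numerical failures exit 3.
"""


class RrmBindKitError(Exception):
    """Base class for all package-specific errors."""


class InputError(RrmBindKitError, ValueError):
    """Invalid user input (bad alphabet, out-of-range index, bad config)."""


class SchemaError(InputError):
    """A tabular file does not match the documented schema."""


class ParseError(InputError):
    """A sequence or structure file could not be parsed."""


class StructureError(InputError):
    """A dot-bracket string is unbalanced or inconsistent with its sequence."""


class UnobservedPairError(RrmBindKitError, KeyError):
    """A (position, residue) pair was queried on a pseudocount-free model
    that never observed it; the probability is undefined, not zero."""


class NumericalError(RrmBindKitError, RuntimeError):
    """An integrator, root bracketing, or optimizer failed."""


class DegenerateDataError(NumericalError):
    """The data carry no signal to fit (e.g. an all-zero sensorgram)."""
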