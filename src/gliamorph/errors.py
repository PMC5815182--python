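"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: validation problems (bad parameters,
inconsistent inputs) exit 2, I/O problems exit 3, computation failures exit 4.
"""


class GliamorphError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(GliamorphError):
    """Invalid parameters, malformed ROI definitions, inconsistent shapes."""

    exit_code = 2


class InputError(GliamorphError):
    """Unreadable or undecodable input files."""

    exit_code = 3


class ComputationError(GliamorphError):
    """A pipeline stage failed to produce a usable result."""

    exit_code = 4
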