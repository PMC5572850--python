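"""Exception hierarchy shared across the package.

Exit codes used by the command-line front end: 2 usage, 3 data format,
4 internal consistency.
"""


class CernetError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class UsageError(CernetError):
    """Invalid arguments, options or call sequence."""

    exit_code = 2


class DataFormatError(CernetError):
    """Malformed or empty input files."""

    exit_code = 3


class ConsistencyError(CernetError):
    """Internal contradiction in otherwise well-formed data."""

    exit_code = 4


class ScenarioError(UsageError):
    """Infeasible or invalid simulation scenario."""


class InsufficientDataError(DataFormatError):
    """Too little data to carry out the requested computation."""
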