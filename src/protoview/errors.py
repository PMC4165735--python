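"""Exception hierarchy shared by all pipeline stages.

The command-line driver maps these onto distinct exit codes so shell
pipelines can tell a malformed input file from a violated internal
contract.
"""


class ProtoviewError(Exception):
    """Base class for all package errors."""


class DataError(ProtoviewError):
    """Input data is unusable (empty database, missing artifact, ...)."""


class FormatError(DataError):
    """A file exists but cannot be parsed as the expected format."""


class DegenerateModelError(DataError):
    """A structure has no usable spatial extent (e.g. coincident atoms)."""


class ParameterError(ProtoviewError):
    """A user-supplied parameter is out of its valid range."""


class ContractError(ProtoviewError):
    """An internal pre/post-condition was violated by the caller."""
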