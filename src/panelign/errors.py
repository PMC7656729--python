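"""Typed error hierarchy.

Every error carries enough location detail (gene, sample, line, column) for a
caller to act on it; the CLI maps these classes onto distinct exit codes.
"""


class PanelignError(Exception):
    """Base class for all package errors."""


class FormatError(PanelignError):
    """A file does not conform to its declared format (missing column/section)."""


class ValidationError(PanelignError):
    """Well-formed input carrying invalid content (negative value, duplicate id)."""


class ContractError(PanelignError):
    """An operation was called outside its contract (bad argument, mismatch)."""


class InsufficientDataError(PanelignError):
    """Too few genes/samples/modules for the operation to be meaningful."""


class DegenerateInputError(PanelignError):
    """Input is technically valid but numerically degenerate (constant matrix)."""


class NoCandidateError(PanelignError):
    """No admissible probe/window candidate exists for the input sequence."""


class DataError(PanelignError):
    """Data violates a run-time assumption (e.g. zero housekeeping count)."""


class UnresolvableError(PanelignError):
    """Panel conflicts remain and no alternative probes are left."""


class NonConvergenceError(PanelignError):
    """An iterative procedure exhausted its round budget."""
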