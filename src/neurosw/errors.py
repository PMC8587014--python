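"""Exception hierarchy.

All package-specific failures derive from :class:`NeuroSWError` so callers
(and the CLI) can distinguish data/configuration problems from genuine bugs.
"""


class NeuroSWError(Exception):
    """Base class for all neurosw errors."""


class InvalidSpecError(NeuroSWError, ValueError):
    """A topology/cohort/pipeline specification violates its invariants."""


class TooShortError(NeuroSWError, ValueError):
    """A time series is too short for the requested operation (e.g. FIR warm-up)."""


class InsufficientDataError(NeuroSWError, RuntimeError):
    """After epoch rejection, fewer data remain than the analysis requires."""


class InvalidBandError(NeuroSWError, ValueError):
    """A frequency band contains no spectral bins or lies outside [0, fs/2)."""


class UndefinedMetricError(NeuroSWError, ValueError):
    """A graph metric is undefined for the given input (e.g. all-zero weights)."""


class DisconnectedGraphError(NeuroSWError, ValueError):
    """Zero-weight edges disconnect the graph; path length is infinite."""


class IncompleteDesignError(NeuroSWError, ValueError):
    """A subject is missing one or more of the seven canonical bands."""
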