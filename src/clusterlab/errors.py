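"""Exception hierarchy.

Every error raised on bad user input derives from ``ValueError`` so that
callers who do not care about the fine-grained class can catch the obvious
thing; computational failures derive from ``RuntimeError``.
"""


class ClusterlabError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(ClusterlabError, ValueError):
    """An argument violates a documented precondition."""


class InsufficientDataError(ClusterlabError, ValueError):
    """Not enough observations to compute the requested quantity."""


class DegenerateHistogramError(ClusterlabError, ValueError):
    """Histogram has fewer than two occupied bins; no threshold exists."""


class FitFailureError(ClusterlabError, RuntimeError):
    """A curve fit did not converge or the response carries no signal."""


class InsufficientEventsError(ClusterlabError, ValueError):
    """A flow-cytometry gate contains fewer events than the required minimum."""


class InvalidDataError(ClusterlabError, ValueError):
    """Data values make the requested statistic undefined (e.g. all <= 0)."""


class UndefinedCorrelationError(ClusterlabError, ValueError):
    """Correlation undefined because one variable is constant."""
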