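"""Exception hierarchy shared across the package.

Exit codes mirror the CLI contract: 3 for malformed or inconsistent input
data, 4 for statistically degenerate situations (a unimodal survival
distribution, an empty response class) where no defensible answer exists.
"""


class CoreMarkersError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class DataError(CoreMarkersError):
    """Malformed, inconsistent, or out-of-contract input data."""

    exit_code = 3


class DegenerateStatisticsError(CoreMarkersError):
    """The requested statistic is undefined on this input."""

    exit_code = 4


class UnimodalSurvivalError(DegenerateStatisticsError):
    """Survival times show no defensible two-mode structure.

    Raised instead of guessing a threshold: callers should not binarize
    the cohort by survival when the fitted mixture is indistinguishable
    from a single mode.
    """


class EmptyClassError(DegenerateStatisticsError):
    """An operation requiring both responder classes saw only one."""
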