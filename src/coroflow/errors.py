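"""Exception hierarchy.

All coroflow errors derive from :class:`CoroflowError` so callers can catch the
package's failures with a single except clause while still distinguishing the
standard-library category (``ValueError``, ``KeyError``, ``RuntimeError``).
"""


class CoroflowError(Exception):
    """Base class for all coroflow errors."""


class ParseError(CoroflowError, ValueError):
    """A tree file does not conform to the JSON/CSV dialect."""


class TopologyError(CoroflowError, ValueError):
    """The branch collection does not form a valid rooted tree."""


class GeometryError(CoroflowError, ValueError):
    """A geometric edit (stenosis, stent) does not fit on its branch."""


class BranchNotFoundError(CoroflowError, KeyError):
    """A branch id does not exist in the tree."""


class NoLesionError(CoroflowError, ValueError):
    """No interior lumen-area minimum exists in the requested window."""


class ConvergenceError(CoroflowError, RuntimeError):
    """The flow solver or calibration loop failed to converge.

    Carries ``residual_history`` (list of floats) for diagnosis.
    """

    def __init__(self, message: str, residual_history=None):
        super().__init__(message)
        self.residual_history = list(residual_history or [])


class InsufficientDataError(CoroflowError, ValueError):
    """Too few observations for the requested statistic."""


class DegenerateDataError(CoroflowError, ValueError):
    """Input data leave a statistic undefined (zero variance, empty class)."""
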