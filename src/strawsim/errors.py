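"""Exception hierarchy.

All package errors derive from :class:`StrawsimError` so callers can catch
one base class; the subclasses also derive from ``ValueError`` because every
failure here is ultimately a bad input or an estimation on degenerate data.
"""


class StrawsimError(Exception):
    """Base class for all strawsim errors."""


class InputError(StrawsimError, ValueError):
    """Invalid or inconsistent model input (bad value, date gap, window mismatch)."""


class EstimationError(StrawsimError, ValueError):
    """A statistical estimate cannot be formed (degenerate regressors, zero variance)."""


class ScenarioError(StrawsimError, ValueError):
    """A synthetic-scenario specification is infeasible."""
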