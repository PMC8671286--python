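"""Exception hierarchy.

``DomainError`` covers precondition violations (inadmissible states, parameters
outside the range a formula is valid for); ``NumericsError`` covers failures of
a numerical procedure on valid inputs and carries the last valid state when the
integrator produced one.
"""


class DomainError(ValueError):
    """Input outside the mathematical domain of an operation."""


class AdmissibilityError(DomainError):
    """A state violates the admissibility constraints."""


class NumericsError(RuntimeError):
    """A numerical routine failed; ``last_state`` holds the last valid state."""

    def __init__(self, message, last_state=None, last_time=None):
        super().__init__(message)
        self.last_state = last_state
        self.last_time = last_time
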