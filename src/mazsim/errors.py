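"""Exception hierarchy for mazsim."""


class MazsimError(Exception):
    """Base class for all mazsim errors."""


class ParameterError(MazsimError, ValueError):
    """A kinetic/coupling parameter violates its constraints."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class StateError(MazsimError, ValueError):
    """A molecular state is corrupted (e.g. negative counts)."""


class InsufficientDataError(MazsimError, ValueError):
    """Too few observations for the requested estimator."""


class RecodingInfeasibleError(MazsimError, RuntimeError):
    """No synonymous codon assignment removes all ACA sites."""

    def __init__(self, stuck_positions, message=None):
        self.stuck_positions = list(stuck_positions)
        super().__init__(
            message
            or f"no synonymous recoding removes ACA sites at {self.stuck_positions}"
        )
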