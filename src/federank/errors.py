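"""Exception hierarchy shared by all engine layers."""


class FederankError(Exception):
    """Base class for all errors raised by federank."""


class RegistryError(FederankError):
    """Invalid registration, dangling reference or malformed registry document."""


class ScoringError(FederankError):
    """Invalid normalization input or weight configuration."""


class JoinError(FederankError):
    """Infeasible join: unbound attribute, bad k, missing record field."""


class PlanError(FederankError):
    """No feasible plan, disconnected query or missing statistics."""


class ExplorationError(FederankError):
    """Invalid navigation step or expansion on the history tree."""


class AdapterError(FederankError):
    """Service invocation failure: missing input binding or bad k."""


class SessionError(FederankError):
    """Malformed or failing session script.

    ``action_index`` is the 1-based position of the offending action, or
    ``None`` when the script failed to load at all.
    """

    def __init__(self, message, action_index=None):
        super().__init__(message)
        self.action_index = action_index
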