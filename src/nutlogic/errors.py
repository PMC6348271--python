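"""Exception hierarchy for nutlogic."""


class NutlogicError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NutlogicError):
    """A simulation configuration references unknown components, crosstalk
    ids, or is otherwise unusable (e.g. an empty condition sequence)."""


class ModelConsistencyError(NutlogicError):
    """The model definition itself is broken: duplicate component names,
    dangling rule references, out-of-domain values, fields that do not
    exist for a component kind."""


class ModelFormatError(NutlogicError):
    """A serialized model document violates the expected schema."""


class OscillationError(NutlogicError):
    """No logical steady state was reached within the sweep budget.

    Carries the change traces of the last two sweeps so the conflicting
    rules can be identified.
    """

    def __init__(self, message, trace=None, step=None):
        super().__init__(message)
        self.trace = trace or []
        self.step = step
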