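"""Exception and warning types shared across the pipeline."""


class ConfigurationError(ValueError):
    """A cohort spec, fit config or CLI config violates its invariants."""


class DataError(ValueError):
    """Input data violate a precondition (shape, finiteness, emptiness)."""


class AnalysisError(RuntimeError):
    """An analysis step cannot proceed (e.g. an empty treatment arm)."""


class ConvergenceWarning(UserWarning):
    """An iterative fit stopped without meeting its tolerance."""
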