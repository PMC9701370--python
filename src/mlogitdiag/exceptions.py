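"""Exception hierarchy for mlogitdiag."""


class MlogitDiagError(Exception):
    """Base class for all package errors."""


class SchemaError(MlogitDiagError):
    """A required column is missing or malformed in an input table."""


class ValidationError(MlogitDiagError):
    """A value violates a domain invariant (bad level, bad count, ...)."""


class LinkageError(MlogitDiagError):
    """Records and the cluster table do not link up consistently."""


class SeparationError(MlogitDiagError):
    """The likelihood has no finite maximiser (complete separation)."""


class ConvergenceError(MlogitDiagError):
    """The optimiser failed to converge within the iteration budget."""

    def __init__(self, message, last_beta=None):
        super().__init__(message)
        self.last_beta = last_beta
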