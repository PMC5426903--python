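"""Exception hierarchy for memokin."""


class MemokinError(Exception):
    """Base class for all memokin errors."""


class UnderdeterminedDataError(MemokinError):
    """Fewer distinct timepoints than free parameters."""


class ConvergenceError(MemokinError):
    """An optimiser failed to converge across all multistarts."""


class InfeasibleParameterError(MemokinError):
    """A proposed parameter point admits no stationary state.

    Raised by the steady-state resolution when no death rate (or division
    rate) in the admissible range balances the population, or when the
    requested Ki67-high fraction cannot be met.  The fitters catch this and
    treat the point as rejected; ``violation`` is a nonnegative measure of
    how badly the constraint fails, used to grade the rejection penalty so
    optimisers can descend back into the feasible region.
    """

    def __init__(self, message: str, violation: float = 1.0):
        super().__init__(message)
        self.violation = float(violation)


class ModelDomainError(MemokinError):
    """The model left its valid region during integration (e.g. the memory
    pool dropped to the incumbent population size)."""


class SchemaError(MemokinError):
    """Input table is missing a required column or has invalid values."""
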