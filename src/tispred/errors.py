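"""Exception types shared across the package."""


class TispredError(Exception):
    """Base class for all package-specific errors."""


class InvalidAlphabetError(TispredError, ValueError):
    """Sequence contains a character outside {A, C, G, T, N}."""


class WindowOutOfBoundsError(TispredError, ValueError):
    """Requested window does not fit inside the source sequence."""


class ConfigurationError(TispredError, ValueError):
    """Inconsistent or infeasible configuration."""


class ShortfallError(TispredError, ValueError):
    """Not enough eligible candidates to satisfy a sampling quota."""


class UndefinedMetricError(TispredError, ZeroDivisionError):
    """A ratio metric has a zero denominator."""


class TrainingDivergedError(TispredError, ArithmeticError):
    """Network training produced a non-finite loss."""

    def __init__(self, epoch: int, learning_rate: float):
        self.epoch = epoch
        self.learning_rate = learning_rate
        super().__init__(
            f"non-finite training loss at epoch {epoch} "
            f"(learning_rate={learning_rate}); lower the learning rate"
        )
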