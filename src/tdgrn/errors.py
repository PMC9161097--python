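"""Exception hierarchy for tdgrn."""


class TDGRNError(Exception):
    """Base class for all tdgrn errors."""


class LagTooLargeError(TDGRNError):
    """A requested lag leaves fewer than three overlapping samples."""


class DomainError(TDGRNError):
    """A complex power with zero base and non-positive exponent."""


class DivergenceError(TDGRNError):
    """A simulated trajectory exceeded the overflow guard."""

    def __init__(self, step: int, value: float):
        self.step = step
        self.value = value
        super().__init__(
            f"trajectory diverged at Euler step {step} (|value| = {value:.3g})"
        )


class ConfigError(TDGRNError):
    """Invalid pipeline or optimizer configuration."""


class GeneMismatchError(TDGRNError):
    """Two networks being compared carry different gene-id sets."""
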