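"""Exception types shared across the toolkit."""


class SnrsError(Exception):
    """Base class for all toolkit errors."""


class ConfigError(SnrsError, ValueError):
    """An invalid simulation or pipeline configuration."""


class GenerationError(SnrsError, RuntimeError):
    """Synthetic data generation failed (e.g. barcode collision)."""


class StateError(SnrsError, ValueError):
    """A matrix is in the wrong normalization state for an operation."""


class EmptyInputError(SnrsError, ValueError):
    """An operation received an empty input it cannot handle."""


class TieError(SnrsError, RuntimeError):
    """A clustering decision is tied and cannot be resolved.

    Raised e.g. when the baseline population splits exactly 50/50
    between the two ploidy clusters; rerun with more baseline cells
    or a cleaner baseline.
    """
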