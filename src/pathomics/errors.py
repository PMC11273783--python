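"""Typed exceptions raised across the pipeline."""


class PathomicsError(Exception):
    """Base class for pipeline errors."""


class ConfigurationError(PathomicsError):
    """A parameter or configuration value is invalid (e.g. rank-deficient
    stain matrix, negative propagation regularization)."""


class GenerationError(PathomicsError):
    """The synthetic cohort generator could not satisfy its constraints
    (e.g. nuclei placement exceeded the retry budget)."""


class IntegrityError(PathomicsError):
    """A cross-compartment invariant was violated (e.g. cell/nuclei label
    sets disagree)."""


class StageError(PathomicsError):
    """A pipeline stage failed; carries the stage name and offending item."""

    def __init__(self, stage: str, item: str, message: str):
        self.stage = stage
        self.item = item
        super().__init__(f"stage '{stage}' failed on '{item}': {message}")
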