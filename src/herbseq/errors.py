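"""Exception hierarchy for herbseq."""


class HerbseqError(Exception):
    """Base class for all herbseq errors."""


class ConfigError(HerbseqError):
    """Invalid run configuration (bad thresholds, barcode collisions, ...)."""


class UndefinedProfileError(HerbseqError):
    """A fragment-size profile with zero total molarity has no defined fractions."""


class SaturationError(HerbseqError):
    """K80 distance undefined: observed divergence is beyond the model's range."""


class DatabaseValidationError(HerbseqError):
    """Reference database lacks the within/between-section distance gap."""

    def __init__(self, message: str, section_pair: tuple[str, str] | None = None):
        super().__init__(message)
        self.section_pair = section_pair


class StageError(HerbseqError):
    """A pipeline stage failed; carries the stage and sample names."""

    def __init__(self, stage: str, sample: str, message: str):
        super().__init__(f"stage {stage!r} failed for sample {sample!r}: {message}")
        self.stage = stage
        self.sample = sample
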