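"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A configuration value is invalid; the message names the offending field."""


class EmptyMaskError(ValueError):
    """An organ mask contains no positive voxel (upstream segmentation failure)."""


class UndefinedMetricError(ValueError):
    """A requested metric has a zero denominator."""


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
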