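"""Exception hierarchy for deepeeg."""


class DeepEEGError(Exception):
    """Base class for all package-specific errors."""


class UnsupportedFormatError(DeepEEGError):
    """File is readable but uses a feature this package does not support."""


class AnnotationParseError(DeepEEGError):
    """Seizure-annotation summary file is malformed."""


class IncompatibleDatasetError(DeepEEGError):
    """Segment-dataset container has a wrong or unreadable header."""


class ConfigurationError(DeepEEGError):
    """Invalid configuration value or combination."""


class ShapeError(ConfigurationError):
    """Architecture cannot be built for the given input shape."""


class DegenerateChannelError(DeepEEGError):
    """A channel has zero variance and cannot be standardized."""

    def __init__(self, channels):
        self.channels = list(channels)
        super().__init__(
            f"constant channel(s) {self.channels}: standard deviation is zero, "
            "z-score normalization undefined"
        )


class TrainingDivergedError(DeepEEGError):
    """Loss became non-finite during optimization."""

    def __init__(self, epoch, batch, value):
        self.epoch = epoch
        self.batch = batch
        super().__init__(
            f"non-finite loss ({value}) at epoch {epoch}, batch {batch}"
        )
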