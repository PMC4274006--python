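class SnptyperError(Exception):
    """Base class for pipeline errors."""


class ConfigError(SnptyperError):
    """Invalid configuration or generator request (CLI exit code 2)."""


class UsageError(SnptyperError):
    """Operation called with inconsistent inputs."""


class StageError(SnptyperError):
    """A pipeline stage failed (CLI exit code 3)."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
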