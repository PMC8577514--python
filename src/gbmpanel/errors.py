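"""Exception types shared across the pipeline stages."""


class GbmPanelError(Exception):
    """Base class for all package errors."""


class ValidationError(GbmPanelError):
    """An input, configuration, or contract precondition was violated."""


class EmptyPanelError(GbmPanelError):
    """No gene reached the selection frequency threshold.

    Carries ``max_count``, the highest frequency observed, so callers can
    report how far the best gene fell short.
    """

    def __init__(self, threshold: int, max_count: int):
        self.threshold = threshold
        self.max_count = max_count
        super().__init__(
            f"no gene reached the frequency threshold {threshold} "
            f"(maximum observed count: {max_count})"
        )


class PipelineStageError(GbmPanelError):
    """A pipeline stage failed; names the stage and chains the cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
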