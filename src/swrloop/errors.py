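"""Exception hierarchy for the swrloop pipeline."""


class SwrLoopError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(SwrLoopError, ValueError):
    """A configuration value is out of its admissible range."""


class DegenerateSignalError(SwrLoopError, ValueError):
    """A signal has zero variance where a spread estimate is required."""


class CorruptBundleError(SwrLoopError, IOError):
    """A recording bundle on disk is inconsistent with its sidecar metadata."""


class PipelineStageError(SwrLoopError, RuntimeError):
    """A pipeline stage failed; carries the stage name.

    ``stage`` names the step (e.g. ``"stream_detect"``) so end-to-end runs
    report where they died rather than a bare traceback.
    """

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
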