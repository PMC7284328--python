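"""Exception hierarchy shared by the pipeline stages."""


class DetectError(Exception):
    """Base class for all pipeline errors."""


class InvalidArgumentError(DetectError, ValueError):
    """A caller-supplied argument violates a precondition."""


class FormatError(DetectError, ValueError):
    """A file does not conform to the expected on-disk format."""


class NoBeatsError(DetectError):
    """A segment contains no detectable heartbeat."""


class BeatRejectedError(DetectError):
    """A single beat failed a fiducial sub-locator and is discarded."""


class StageError(DetectError):
    """A pipeline stage aborted; carries the stage name and offending item."""

    def __init__(self, stage: str, detail: str):
        self.stage = stage
        self.detail = detail
        super().__init__(f"[{stage}] {detail}")
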