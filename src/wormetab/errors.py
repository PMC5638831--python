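"""Exception hierarchy.

``WormetabError`` marks user-facing input/usage problems (CLI exit code 1);
anything else escaping the library is treated as internal (exit code 2).
"""


class WormetabError(Exception):
    """Invalid input or usage of the pipeline."""


class InputError(WormetabError):
    """Malformed or missing input data."""


class ConfigError(WormetabError):
    """Invalid run configuration."""


class PipelineError(WormetabError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause
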