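"""Exception hierarchy shared across the pipeline stages."""


class MethomicsError(Exception):
    """Base class for all package errors."""


class ConfigError(MethomicsError):
    """Invalid configuration value; the message names the offending field."""


class ParseError(MethomicsError):
    """Malformed input file; the message carries the file and line number."""


class DataError(MethomicsError):
    """Well-formed input whose content violates a contract (e.g. meth > total)."""


class AnnotationError(MethomicsError):
    """Invalid genomic annotation (e.g. interval with start > end)."""


class PipelineError(MethomicsError):
    """A stage of the end-to-end pipeline failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
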