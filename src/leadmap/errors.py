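"""Exception hierarchy for the leadmap pipeline."""


class LeadmapError(Exception):
    """Base class for all leadmap errors."""


class SchemaError(LeadmapError):
    """A survey table does not conform to the documented column schema."""


class ValidationError(LeadmapError):
    """A record carries values outside the permitted domain."""


class ConfigurationError(LeadmapError):
    """A cohort or run configuration is degenerate or inconsistent."""


class BoundaryError(LeadmapError):
    """A boundary restriction produced an empty or undefined network."""


class PipelineError(LeadmapError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
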