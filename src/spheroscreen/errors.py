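"""Exception types shared across the pipeline stages."""


class SpheroScreenError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SpheroScreenError, ValueError):
    """An invalid simulation or run configuration."""


class RenderingError(SpheroScreenError, ValueError):
    """A spheroid cannot be rendered into the requested frame."""


class DegenerateAssayError(SpheroScreenError, ValueError):
    """Control fluorescence does not exceed the basal signal."""


class PipelineError(SpheroScreenError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
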