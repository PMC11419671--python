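"""Exception hierarchy shared across the pipeline."""


class TrlmapError(Exception):
    """Base class for all trlmap errors."""


class FormatError(TrlmapError):
    """A file does not conform to its declared dialect or schema."""


class ConfigError(TrlmapError):
    """Invalid or inconsistent configuration."""


class InputError(TrlmapError):
    """Invalid numerical or tabular input to an operation."""


class PipelineError(TrlmapError):
    """A pipeline stage failed; the message names the stage."""
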