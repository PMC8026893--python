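"""Exception types shared across the pipeline."""


class InvalidConfigError(ValueError):
    """A configuration value violates a documented constraint."""


class PipelineError(RuntimeError):
    """A pipeline stage cannot produce output (e.g. no epochs, no survivors)."""
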