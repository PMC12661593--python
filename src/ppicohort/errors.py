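"""Exception types shared across the package."""


class InputFormatError(ValueError):
    """A file does not conform to its declared dialect (bad field count,
    non-numeric score, duplicate column, ...). The message names the
    offending line or column where possible."""


class GenerationError(RuntimeError):
    """Synthetic-data generation could not satisfy its configuration
    (e.g. an unattainable module overlap target)."""
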