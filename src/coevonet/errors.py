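class ConfigurationError(ValueError):
    """Model parameters are inconsistent, out of range, or infeasible."""


class InternalModelError(RuntimeError):
    """An internal consistency guard failed; indicates a bug, not bad input."""
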