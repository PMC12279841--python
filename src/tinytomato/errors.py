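"""Package-wide exception types."""


class InvalidBoxError(ValueError):
    """A bounding box has non-positive width or height."""


class ConfigurationError(ValueError):
    """A configuration value violates its documented constraints."""


class FusionStateError(RuntimeError):
    """A reparameterized block was used in a mode it is not in."""
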