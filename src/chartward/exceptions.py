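"""Package-wide exception types."""


class ConfigurationError(ValueError):
    """A configuration value is invalid; the message names the field."""


class SchemaError(ValueError):
    """An input table violates its schema; the message cites column/row."""


class VersionMismatchError(RuntimeError):
    """Model and preprocessing version tags disagree."""


class FeatureMismatchError(KeyError):
    """Prediction-time features do not match the fitted model's features."""
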