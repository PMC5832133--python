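"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """Invalid paradigm, profile, or pipeline configuration."""


class InfeasibleDesignError(ConfigurationError):
    """A requested design cannot be satisfied (e.g. too many target repetitions)."""


class DataFormatError(ValueError):
    """A persisted artifact is malformed or inconsistent with its sidecar."""
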