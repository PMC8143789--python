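class ConfigurationError(ValueError):
    """A model configuration is invalid (unknown kind, bad parameter, ...)."""


class ConfigFileError(ConfigurationError):
    """A config file failed schema validation; collects all violations."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {v}" for v in self.violations))
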