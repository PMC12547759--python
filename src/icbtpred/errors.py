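"""Exception types shared across the package."""


class ConfigError(ValueError):
    """A configuration value violates its invariant; names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid configuration field '{field}': {message}")


class CohortParseError(ValueError):
    """A cohort or message file failed to parse/validate; carries a line number."""

    def __init__(self, line: int, message: str):
        self.line = line
        super().__init__(f"line {line}: {message}")


class MissingDataError(ValueError):
    """An operation that requires complete data received missing values."""
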