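"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A profile, config or rule set is internally inconsistent."""


class ValidationError(ValueError):
    """Input data violate a declared invariant.

    ``line`` carries the 1-based line number of the first offending row
    when the error arises while parsing a file.
    """

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line
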