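"""Exception hierarchy shared across the toolkit."""


class MarktaxError(Exception):
    """Base class for all marktax errors."""


class ConfigurationError(MarktaxError):
    """A parameter set is incomplete or internally inconsistent."""


class ParseError(MarktaxError):
    """An input file or string could not be parsed.

    Carries an optional 1-based line number for tabular inputs.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ConsistencyError(MarktaxError):
    """Two inputs that must agree (e.g. hits vs. genome universe) do not."""


class UndefinedIdentityError(MarktaxError):
    """A percent identity has a zero denominator (e.g. disjoint gap patterns)."""
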