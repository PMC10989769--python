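"""Exception types shared across the toolkit."""


class RamavitError(Exception):
    """Base class for all toolkit errors."""


class ParseError(RamavitError):
    """Raised when a spectral table or manifest cannot be parsed.

    Carries the offending file and, where known, the 1-based line number.
    """

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f"{path}"
            if line is not None:
                loc += f":{line}"
            loc = f" [{loc}]"
        super().__init__(f"{message}{loc}")
        self.path = path
        self.line = line
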