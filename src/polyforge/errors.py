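"""Exception hierarchy.

``ForgeError`` is the base; ``InputError`` marks problems caused by user
input (bad files, infeasible specs) and maps to exit code 2 in the CLI,
everything else maps to exit code 1.
"""


class ForgeError(Exception):
    """Base class for all polyforge errors."""


class InputError(ForgeError):
    """User-supplied input is invalid (file content, spec, arguments)."""


class ParseError(InputError):
    """A file could not be parsed; carries file and line context."""

    def __init__(self, message, path=None, line=None):
        ctx = ""
        if path is not None:
            ctx = f"{path}"
            if line is not None:
                ctx += f":{line}"
            ctx += ": "
        super().__init__(ctx + message)
        self.path = path
        self.line = line


class BuildError(ForgeError):
    """Coordinate generation failed (placement, minimization, ...)."""
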