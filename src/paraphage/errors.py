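"""Exception hierarchy shared across the package."""


class ParaphageError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(ParaphageError, ValueError):
    """An argument violates an operation's preconditions."""


class TableFormatError(ParaphageError, ValueError):
    """A tabular input is structurally unusable (e.g. a required column is missing)."""


class RowError(ParaphageError, ValueError):
    """One or more rows of a tabular input are malformed.

    Carries ``rows``: a list of ``(line_number, identifier, message)`` tuples.
    """

    def __init__(self, rows):
        self.rows = list(rows)
        detail = "; ".join(f"line {ln} ({rid}): {msg}" for ln, rid, msg in self.rows)
        super().__init__(f"{len(self.rows)} malformed row(s): {detail}")


class GenerationError(ParaphageError, RuntimeError):
    """The synthetic community cannot be realized under the given configuration."""


class JoinError(ParaphageError, KeyError):
    """Identifiers cannot be joined across tables.

    Carries ``ids``: the offending identifiers.
    """

    def __init__(self, ids, context=""):
        self.ids = sorted(ids)
        msg = f"unknown identifier(s){' in ' + context if context else ''}: {', '.join(self.ids)}"
        super().__init__(msg)

    def __str__(self):  # KeyError quotes its arg; keep the plain message
        return self.args[0]


class PipelineConfigError(ParaphageError, ValueError):
    """A pipeline configuration is invalid; the message names the field."""
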