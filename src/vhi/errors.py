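"""Exception hierarchy for the VHI pipeline.

Every error raised on bad user input derives from :class:`VHIError` so
callers (and the CLI) can distinguish data problems from genuine bugs.
"""


class VHIError(Exception):
    """Base class for all errors raised by this package."""


class InvalidInputError(VHIError, ValueError):
    """Input data violates a documented precondition."""


class DegenerateInputError(InvalidInputError):
    """Input is formally valid but statistically degenerate (e.g. constant)."""


class MissingStandardError(VHIError, KeyError):
    """No health standard is available for an (age, bed) stratum."""

    def __init__(self, age_wk, bed):
        self.age_wk = age_wk
        self.bed = bed
        super().__init__(f"no health standard for age {age_wk} wk, bed {bed!r}")


class NormalizationError(VHIError):
    """Percentile-mode normalization is impossible (e.g. no LZR animals)."""


class ModelInconsistencyError(VHIError):
    """The forward mechanics model has no solution at a pressure step."""


class SchemaError(VHIError, ValueError):
    """A CSV file failed schema validation.

    Carries enough context (file, line, column) to point at the offending
    cell in an editor.
    """

    def __init__(self, message, *, path=None, line=None, column=None):
        self.path = path
        self.line = line
        self.column = column
        loc = []
        if path is not None:
            loc.append(str(path))
        if line is not None:
            loc.append(f"line {line}")
        if column is not None:
            loc.append(f"column {column!r}")
        prefix = ", ".join(loc)
        super().__init__(f"{prefix}: {message}" if prefix else message)
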