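"""Exception hierarchy for the spyquest engine."""


class SpyquestError(Exception):
    """Base class for all spyquest errors."""


class SchemaTooSmall(SpyquestError):
    """The attribute product space cannot hold the requested number of distinct suspects."""


class UnknownProperty(SpyquestError):
    """A constraint or label names a property absent from the schema."""


class UnknownValue(SpyquestError):
    """A constraint or label names a value outside the property's domain."""


class NegativeElimination(SpyquestError):
    """A transcript records a negative elimination count."""


class RoomMismatch(SpyquestError):
    """A transcript's room reference does not match the room it is replayed against."""


class NoClassifiableQuestion(SpyquestError):
    """A transcript contains no question the classifier can assign a label to."""


class NoInformativeQuestion(SpyquestError):
    """Every unasked (property, value) pair is held by all or none of the remaining suspects."""


class SchemaVersionMismatch(SpyquestError):
    """A transcript file declares an unsupported format version."""


class MalformedRecord(SpyquestError):
    """A transcript record is missing required fields or has the wrong shape."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class TooFewMinoritySamples(SpyquestError):
    """SMOTE needs at least two minority-class samples to interpolate between."""


class NonConvergence(SpyquestError):
    """Maximum-likelihood fit did not converge; carries the last iterate."""

    def __init__(self, message: str, params=None):
        self.params = params
        super().__init__(message)


class EmptyTestSet(SpyquestError):
    """Classifier evaluation requires a non-empty test set."""
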