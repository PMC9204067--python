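"""Exception hierarchy shared across the package."""


class MuriclockError(Exception):
    """Base class for all muriclock errors."""


class BetaParseError(MuriclockError):
    """A cell in a beta matrix failed to parse or is out of [0, 1]."""


class SchemaError(MuriclockError):
    """A required column is missing or mistyped in a tabular input."""


class ValidationError(MuriclockError):
    """An input violates a structural invariant (duplicate ids, bad enum...)."""


class EmptyCohortError(MuriclockError):
    """QC removed every sample."""


class DegenerateGroupError(MuriclockError):
    """A (strain, sex) group has a single distinct age: min-max scaling undefined."""


class DegeneratePredictorError(MuriclockError):
    """The predictor variable has zero variance."""


class UndefinedCorrelationError(MuriclockError):
    """Pearson correlation undefined (zero variance in one of the vectors)."""


class UnderpoweredDesignError(MuriclockError):
    """A group is too small for the requested test."""


class PredictionError(MuriclockError):
    """A clock cannot produce a prediction for the given sample."""


class ConfigurationError(MuriclockError):
    """Invalid run configuration or model-fitting setup."""
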