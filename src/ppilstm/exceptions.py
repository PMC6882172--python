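"""Exception hierarchy shared across the package."""


class PpiLstmError(Exception):
    """Base class for package errors."""


class ValidationError(PpiLstmError, ValueError):
    """Invalid data: bad shapes, non-finite values, inconsistent arguments."""


class ConfigurationError(PpiLstmError, ValueError):
    """Invalid configuration: bad hyperparameters, incompatible widths."""


class SchemaError(PpiLstmError, ValueError):
    """A delimited table does not match the documented column schema."""


class TrainingError(PpiLstmError, RuntimeError):
    """Optimization failure, e.g. the loss became non-finite."""
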