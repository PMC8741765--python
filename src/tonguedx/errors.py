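"""Exception hierarchy shared across the package.

The CLI maps these onto distinct exit codes so callers can tell a bad
configuration from bad data from a failed training run.
"""


class TongueDxError(Exception):
    """Base class for all package errors."""


class SchemaError(TongueDxError):
    """A record, table or encoding violates the feature vocabulary."""


class ConfigError(TongueDxError):
    """Invalid run, network or cohort configuration."""


class DataError(TongueDxError):
    """Structurally valid input that cannot support the requested operation
    (single-class training set, degenerate splits, ...)."""


class CalibrationError(TongueDxError):
    """Intercept calibration of the cohort label model failed to converge."""


class TrainingError(TongueDxError):
    """Numerical failure during pretraining or fine-tuning."""


class NotFittedError(TongueDxError):
    """Prediction requested from a network that has not been fitted."""
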