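"""Exception hierarchy shared across the package."""


class DkdRiskError(Exception):
    """Base class for all package errors."""


class SchemaError(DkdRiskError):
    """An input file does not match the documented schema."""


class IntegrityError(DkdRiskError):
    """A structural invariant is violated (e.g. duplicate patient ids)."""


class DomainError(DkdRiskError, ValueError):
    """A value lies outside its mathematical or clinical domain."""


class ConfigError(DkdRiskError):
    """A run configuration is infeasible or inconsistent."""


class BoundsError(DomainError):
    """A covariate violates the model's clinical safety bounds."""
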