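"""Exception hierarchy shared across the pipeline."""


class DurasimError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(DurasimError):
    """A configuration value is inconsistent or out of range."""


class GeometryError(DurasimError):
    """A phantom or grid geometry constraint is violated."""


class ValidationError(DurasimError):
    """Input data failed a validation check."""


class SolverError(DurasimError):
    """The linear solver failed to produce a valid solution."""
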