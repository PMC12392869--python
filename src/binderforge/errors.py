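"""Exception hierarchy shared across the pipeline."""


class BinderForgeError(Exception):
    """Base class for all package errors."""


class InvalidInputError(BinderForgeError, ValueError):
    """An argument value violates a documented precondition."""


class ConfigurationError(BinderForgeError, ValueError):
    """A configuration (statistics table, gate manifest, ...) is unusable."""


class DegenerateGeometryError(BinderForgeError, ValueError):
    """Coordinates are rank-deficient or colinear where a frame is needed."""


class IdentifiabilityError(BinderForgeError, ValueError):
    """The data cannot pin down the requested parameters."""


class SchemaError(BinderForgeError, ValueError):
    """A tabular input is missing required columns or contains bad values."""
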