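"""Exception hierarchy shared across the package."""


class GASelectError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(GASelectError, ValueError):
    """A user-supplied option or hyperparameter is invalid."""


class DataError(GASelectError, ValueError):
    """The input data violate a contract the method requires
    (e.g. a single-class label column, or disjoint feature spaces)."""
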