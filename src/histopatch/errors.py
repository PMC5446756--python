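"""Exception types shared across the pipeline."""


class HistopatchError(Exception):
    """Base class for all package errors."""


class ParameterError(HistopatchError, ValueError):
    """A parameter violates its documented domain (e.g. k out of range)."""


class InputError(HistopatchError, ValueError):
    """Input data violates a precondition (e.g. empty patch, negative feature)."""


class ConfigurationError(HistopatchError, ValueError):
    """Inconsistent or unknown configuration (e.g. unknown key, metadata mismatch)."""


class EmptyTissueError(InputError):
    """An image yielded zero non-background patches and cannot be featurized."""
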