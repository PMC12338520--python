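"""Exception hierarchy shared across the package.

``FluoremError`` is the base; the CLI maps :class:`InputError` (and
subclasses) to exit code 1 and everything else unexpected to exit code 2.
"""


class FluoremError(Exception):
    """Base class for all package errors."""


class InputError(FluoremError):
    """Bad user input: files, formats, configuration values."""


class ConfigurationError(InputError):
    """An invalid parameter value or unknown rule name."""


class ModelError(FluoremError):
    """The proteome model cannot be built or is internally inconsistent."""


class DegenerateInputError(FluoremError):
    """A mathematically degenerate input (e.g. all mass on unobservable proteins)."""


class InconsistencyError(FluoremError):
    """Two objects that must share a universe (strings, proteins) do not."""


class CapacityError(FluoremError):
    """A guarded exact computation would exceed its configured size cap."""
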