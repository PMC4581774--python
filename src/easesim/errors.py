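"""Exception types shared across the package."""


class EasesimError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EasesimError):
    """A parameter, schedule, or config file value is invalid."""


class InputError(EasesimError):
    """A runtime input (portfolio, cost, trajectory) violates a precondition."""
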