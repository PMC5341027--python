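"""Exception hierarchy mapped to CLI exit codes."""


class IBCError(Exception):
    """Base class for all ibclust errors."""

    exit_code = 1


class InputValidationError(IBCError):
    """Invalid input data (bad counts, labels, preconditions). Exit code 2."""

    exit_code = 2


class NumericalError(IBCError):
    """Numerical failure inside the sampler. Exit code 3."""

    exit_code = 3


class ConfigError(IBCError):
    """Invalid run configuration. Exit code 4."""

    exit_code = 4
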