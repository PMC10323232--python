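"""Exception hierarchy for the epievents pipeline."""


class EpieventsError(Exception):
    """Base class for all pipeline errors."""


class InvalidInputError(EpieventsError, ValueError):
    """An argument violates a precondition (bad calibration, shape, bounds...)."""


class FormatError(EpieventsError, ValueError):
    """A file on disk does not conform to its expected format."""


class ConfigError(EpieventsError, ValueError):
    """A configuration is internally inconsistent or infeasible."""


class SamplingError(EpieventsError, RuntimeError):
    """A randomised sampling procedure could not satisfy its constraints."""


class SpecError(EpieventsError, ValueError):
    """A network specification is infeasible or mismatched with data."""
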