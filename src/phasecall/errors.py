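"""Exception hierarchy shared by the library and the command-line layer."""


class PhasecallError(Exception):
    """Base class for all phasecall errors."""


class ValidationError(PhasecallError):
    """Invalid input data or configuration (CLI exit code 2)."""


class DesignError(ValidationError):
    """The experimental design does not support the requested operation."""


class ComputationError(PhasecallError):
    """A statistical computation could not be carried out (CLI exit code 3)."""
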