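"""Exception hierarchy."""


class PatchPKError(Exception):
    """Base class for all package errors."""


class ParameterError(PatchPKError, ValueError):
    """A pharmacokinetic parameter is outside its admissible domain."""


class InputError(PatchPKError, ValueError):
    """Malformed runtime input (grids, labels, windows, files)."""


class IdentifiabilityError(PatchPKError, ValueError):
    """A requested estimation setup is structurally non-identifiable."""


class IntegrationError(PatchPKError, RuntimeError):
    """The ODE oracle failed to integrate a segment."""
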