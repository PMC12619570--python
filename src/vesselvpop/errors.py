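"""Exception hierarchy shared across the package."""


class VesselVpopError(Exception):
    """Base class for all package-specific errors."""


class FormatError(VesselVpopError):
    """A file does not conform to the expected dialect (missing columns, bad cells)."""


class DegenerateInputError(VesselVpopError):
    """Input is structurally valid but too degenerate to process (e.g. a single point)."""


class ParameterError(VesselVpopError):
    """An operation was called with an out-of-range or inconsistent parameter."""


class StageError(VesselVpopError):
    """A pipeline stage failed; the message names the stage and the offending entity."""
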