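"""Exception hierarchy for plaquesim."""


class PlaquesimError(Exception):
    """Base class for all package errors."""


class MaskFormatError(PlaquesimError, ValueError):
    """A label mask file is malformed or uses unknown label codes."""


class GeometryError(PlaquesimError, ValueError):
    """A domain geometry violates a structural requirement."""


class ParameterError(PlaquesimError, ValueError):
    """A parameter or configuration value is out of its admissible range."""


class NumericalError(PlaquesimError, RuntimeError):
    """The solver produced non-finite values or hit an instability."""
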