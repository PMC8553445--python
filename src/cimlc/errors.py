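"""Exception hierarchy.

Every error raised on bad user input derives from :class:`CimlcError`, so the
command-line layer can map all of them onto a single exit code.
"""


class CimlcError(Exception):
    """Base class for all validation and modelling errors."""


class ValidationError(CimlcError):
    """Malformed or out-of-range input data (material tables, profiles, ...)."""


class GeometryError(CimlcError):
    """Inconsistent beamline geometry (ordering of planes, leaf behind source)."""


class InsufficientThicknessError(CimlcError):
    """The requested survival path exceeds any chord through the leaf end."""


class EdgeNotFoundError(CimlcError):
    """A dose profile does not cross the requested isodose level."""


class CalibrationRangeError(CimlcError):
    """Calibration queried outside the fitted response range."""
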