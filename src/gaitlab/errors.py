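"""Exception hierarchy."""


class GaitLabError(Exception):
    """Base class for all package errors."""


class InvalidDepthError(GaitLabError, ValueError):
    """A depth value that must be strictly positive was not."""


class BehindCameraError(GaitLabError, ValueError):
    """A 3D point with z <= 0 cannot be projected."""


class DegenerateGeometryError(GaitLabError, ValueError):
    """An angle was requested on coincident or zero-length vectors."""


class LandmarkValidationError(GaitLabError, ValueError):
    """Landmark coordinates or counts violate the 33-joint contract."""


class CatalogLookupError(GaitLabError, KeyError):
    """Unknown clinical test or item number."""


class ScenarioError(GaitLabError, ValueError):
    """Invalid scenario script or out-of-range simulation time."""


class SessionFormatError(GaitLabError, ValueError):
    """A session bundle component failed to parse."""
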