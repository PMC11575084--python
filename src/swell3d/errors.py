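"""Exception hierarchy for the swelling-analysis pipeline."""


class Swell3dError(Exception):
    """Base class for all package errors."""


class MeshFormatError(Swell3dError):
    """A mesh file could not be parsed as the requested/detected format."""


class UnsupportedTopologyError(Swell3dError):
    """The file contains non-triangular cells or other unsupported topology."""


class CapabilityError(Swell3dError):
    """The requested output format cannot represent the requested content."""


class InvalidMeshError(Swell3dError):
    """A TriangleMesh violates its structural invariants."""


class DegenerateLandmarksError(Swell3dError):
    """Landmarks are collinear/coincident and cannot define the canonical frame."""


class InconsistentRoiError(Swell3dError):
    """ROI landmarks define an empty or contradictory region."""


class EmptyRoiError(Swell3dError):
    """No vertices fall inside the region of interest."""


class NonManifoldError(Swell3dError):
    """An edge is shared by three or more faces; hole filling is undefined."""


class NotWatertightError(Swell3dError):
    """A volume was requested for an open mesh without auto-closing."""


class PipelineError(Swell3dError):
    """A pipeline stage failed; carries the stage name and offending file."""

    def __init__(self, stage: str, message: str, path: str | None = None):
        self.stage = stage
        self.path = path
        loc = f" [{path}]" if path else ""
        super().__init__(f"stage '{stage}'{loc}: {message}")
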