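"""Exception hierarchy shared across the package."""


class LigandCloudError(Exception):
    """Base class for all package-specific errors."""


class PDBParseError(LigandCloudError):
    """A multi-model PDB file is malformed (e.g. unequal atom counts)."""


class TopologyParseError(LigandCloudError):
    """A topology table is malformed; message carries the line number."""


class ConfigurationError(LigandCloudError):
    """Inputs are structurally valid but inconsistent with the request."""


class IntegrationError(LigandCloudError):
    """The Langevin integrator produced non-finite coordinates."""


class DegenerateGeometryError(LigandCloudError):
    """A geometric operation received a degenerate (e.g. collinear) input."""
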