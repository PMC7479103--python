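"""Exception hierarchy shared across nervekit modules."""


class NervekitError(Exception):
    """Base class for all nervekit errors."""


class ConfigError(NervekitError, ValueError):
    """Invalid generator or pipeline configuration."""


class DialectError(NervekitError, ValueError):
    """A table does not conform to the documented CSV dialect."""


class TrackFormatError(NervekitError, ValueError):
    """A track table is structurally malformed (duplicates, bad ordering)."""


class GeometryError(NervekitError, ValueError):
    """Degenerate posture geometry (coincident spine points, empty spine)."""


class DegenerateInputError(NervekitError, ValueError):
    """Statistical operation received degenerate input (constant group, n too small)."""
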