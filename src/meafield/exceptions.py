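"""Exception hierarchy for meafield."""


class MeafieldError(Exception):
    """Base class for all meafield errors."""


class GeometryError(MeafieldError, ValueError):
    """Invalid slice geometry or a source/observation outside its domain."""


class SingularityError(MeafieldError, ZeroDivisionError):
    """Observation point coincides with a source (potential diverges)."""


class UnsupportedConfigurationError(MeafieldError, ValueError):
    """A closed-form formula does not exist for the requested configuration."""


class NumericalError(MeafieldError, RuntimeError):
    """A numerical procedure failed (e.g. singular kernel with zero ridge)."""
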