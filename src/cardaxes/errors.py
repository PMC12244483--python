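"""Exception hierarchy shared across the package."""


class CardaxesError(Exception):
    """Base class for all package-specific errors."""


class UsageError(CardaxesError):
    """Invalid arguments: unknown method tag, mismatched lengths, bad ranges."""


class ConfigError(CardaxesError):
    """Malformed configuration: wrong coefficient shape, unresolvable paths."""


class FormatError(CardaxesError):
    """A file parsed, but its contents violate the expected schema."""


class IncompleteMeshError(CardaxesError):
    """A required anatomical region is missing or empty."""

    def __init__(self, region: str, message: str | None = None):
        self.region = region
        super().__init__(message or f"mesh is missing required region {region!r}")


class DegenerateGeometryError(CardaxesError):
    """Geometry without enough rank/extent for the requested computation."""


class FrameError(CardaxesError):
    """A coordinate-frame tag does not match what the operation expects."""
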