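"""Exception and warning types shared across the package."""


class LmwgsError(Exception):
    """Base class for all package errors."""


class InputError(LmwgsError):
    """Malformed or illegal input data (bad characters, empty sequence...)."""


class ValidationError(LmwgsError):
    """A domain object violates one of its invariants."""


class ConfigError(LmwgsError):
    """Invalid or inconsistent pipeline/population configuration."""


class AnnotationError(LmwgsError):
    """A sequence cannot be annotated (no ORF, too short...)."""


class AmbiguousAmplificationError(LmwgsError):
    """A primer binds more than one site in the template."""

    def __init__(self, message: str, positions=None):
        super().__init__(message)
        self.positions = list(positions or [])


class ConsistencyError(LmwgsError):
    """Cross-table references do not agree (orphan variants...)."""


class AtypicalCysteineWarning(UserWarning):
    """A mature subunit does not show the canonical 8-cysteine layout."""
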