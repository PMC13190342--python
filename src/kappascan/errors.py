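"""Exception types shared across the package."""


class KappascanError(Exception):
    """Base class for package errors."""


class AnnotationError(KappascanError):
    """Locus annotation is missing, malformed or violates an invariant."""


class TlxFormatError(KappascanError):
    """A TLX-like junction table is malformed."""


class TrainingError(KappascanError):
    """An RSS model cannot be trained from the given sequences."""


class ScoringError(KappascanError):
    """A sequence cannot be scored under the given RSS model."""


class TransformError(KappascanError):
    """A position has no image under a coordinate transform."""


class ConfigError(KappascanError):
    """A configuration value is out of range or inconsistent."""


class NormalizationError(KappascanError):
    """A junction library cannot be normalized."""
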