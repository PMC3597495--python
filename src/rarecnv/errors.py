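"""Exception hierarchy for the rarecnv package."""


class RareCNVError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(RareCNVError):
    """A configuration value is invalid; the message names the field."""


class ParseError(RareCNVError):
    """A file could not be parsed; the message lists offending lines."""


class LinkageError(RareCNVError):
    """Cross-references between files do not resolve (e.g. missing parent)."""


class IntegrityError(RareCNVError):
    """A packaged resource failed its integrity checks."""


class GenerationError(RareCNVError):
    """Synthetic data could not be generated under the requested constraints."""


class PlacementError(RareCNVError):
    """A random interval could not be placed on the genome."""
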