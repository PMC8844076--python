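"""Exception hierarchy shared across the package."""


class MMTFSError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MMTFSError):
    """A configuration value violates its documented bounds or schema."""


class DataFormatError(MMTFSError):
    """An on-disk table failed to parse or violated a value constraint."""
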