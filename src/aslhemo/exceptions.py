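"""Exception types shared across the package."""


class AslHemoError(Exception):
    """Base class for package errors."""


class DomainError(AslHemoError, ValueError):
    """An input is outside the physical/mathematical domain of an operation."""


class ConfigurationError(AslHemoError, ValueError):
    """A configuration value is inconsistent with the data it is applied to."""


class GridMismatchError(AslHemoError, ValueError):
    """Volumes that must share a voxel grid do not."""
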