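"""Exception hierarchy for colorquant.

All errors derive from :class:`ColorquantError` so callers can catch the
package's failures with a single handler; the subclasses distinguish the
three broad failure classes the command-line layer maps to exit codes
(input, configuration, numerical).
"""


class ColorquantError(Exception):
    """Base class for all colorquant errors."""


class InputError(ColorquantError):
    """Malformed or unreadable input data (images, tables, files)."""


class ImageFormatError(InputError):
    """Image is not 8-bit, not 3-channel, or otherwise not a valid RGB raster."""


class ShapeMismatchError(InputError):
    """Operands have incompatible dimensions."""


class ConfigError(ColorquantError):
    """Invalid or inconsistent run configuration."""


class ContractError(ConfigError):
    """A call violated an interface contract (wrong columns, wrong scaling)."""


class CapacityError(ConfigError):
    """A region of interest is too small for the requested pixel counts."""


class DesignMismatchError(ConfigError):
    """Feature tables are inconsistent with the declared assay design."""


class NumericalError(ColorquantError):
    """A computation is undefined or degenerate for the given data."""


class DegenerateInputError(NumericalError):
    """Data carry no usable variation (constant target, zero range, ...)."""
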