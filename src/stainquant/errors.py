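"""Exception hierarchy for stainquant."""


class StainQuantError(Exception):
    """Base class for all stainquant errors."""


class ParameterError(StainQuantError, ValueError):
    """A configuration or function parameter is out of its valid range."""


class ImageIOError(StainQuantError, OSError):
    """An image file could not be read or written."""


class FormatError(StainQuantError, ValueError):
    """An image file has an unsupported mode or bit depth."""


class DegenerateImageError(StainQuantError, ValueError):
    """An operation that needs intensity contrast received a constant image."""


class MaskConsistencyError(StainQuantError, ValueError):
    """Two masks or reports violate a containment/join contract."""
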