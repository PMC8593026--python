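"""Exception types shared across the package."""


class ConfigError(ValueError):
    """Invalid configuration; the message names the offending field."""


class RasterError(ValueError):
    """Raster input violates a contract (CRS, transform, band count...)."""
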