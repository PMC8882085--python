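"""Exception hierarchy shared across the package."""


class PttQuantError(Exception):
    """Base class for all package-specific errors."""


class DataError(PttQuantError):
    """Invalid measurement data (bad counts, schema violations, orphan rows)."""


class ConfigError(PttQuantError):
    """Invalid configuration (assay geometry, simulation parameters, paths)."""


class SaturationError(DataError):
    """All droplets positive: the Poisson transform is undefined."""


class DegenerateRatioError(DataError):
    """A ratio is requested from a zero or flagged denominator."""
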