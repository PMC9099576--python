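"""Exception types shared across the pipeline stages."""


class SpectraGPError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(SpectraGPError):
    """Invalid configuration value."""


class ScalingError(SpectraGPError):
    """A variance budget cannot accommodate the requested signal share."""


class EmptyDataError(SpectraGPError):
    """No data survived an editing or filtering step."""


class PedigreeCycleError(SpectraGPError):
    """An individual appears among its own ancestors."""


class RankError(SpectraGPError):
    """Fixed-effect equations singular after the identifiability constraint."""


class AlignmentError(SpectraGPError):
    """Per-phenotype fits do not share the same HYS class set."""


class KernelError(SpectraGPError):
    """Kernel construction or decomposition failed validation."""


class DegenerateStatisticError(SpectraGPError):
    """A statistic is undefined on the given input (e.g. zero variance)."""
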