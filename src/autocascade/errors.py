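"""Exception types shared across the toolkit."""


class FormatError(ValueError):
    """A file or array does not conform to the expected volume format."""


class ConfigurationError(ValueError):
    """Invalid configuration value (axis names, sizes, channel counts...)."""


class DegenerateDataError(ValueError):
    """Data without enough variation to support the requested operation."""


class AssemblyError(ValueError):
    """Slice stack and template volume geometries do not match."""


class ContractError(ValueError):
    """A pipeline stage received inputs violating its interface contract."""


class UndefinedMetricError(ValueError):
    """Metric undefined for this input (e.g. Hausdorff of an empty mask)."""


class TrainingDivergenceError(RuntimeError):
    """Non-finite loss encountered during optimisation."""


class PhantomSpecError(ValueError):
    """Phantom geometry cannot be realised on the requested grid."""
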