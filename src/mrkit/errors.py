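"""Exception hierarchy shared across mrkit."""


class MrkitError(Exception):
    """Base class for all mrkit errors."""


class ConfigError(MrkitError):
    """Invalid configuration: bad column mapping, missing settings, bad thresholds."""


class DataError(MrkitError):
    """Input data violates a hard invariant (bad allele, out-of-range frequency, ...)."""


class AnalysisError(MrkitError):
    """An estimator or diagnostic cannot be computed on the given inputs."""
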