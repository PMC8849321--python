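"""Exception hierarchy shared across pioneerkit."""


class PioneerKitError(Exception):
    """Base class for all pioneerkit errors."""


class ParseError(PioneerKitError):
    """A text input (BED, JASPAR PFM, TSV) could not be parsed."""


class ConfigError(PioneerKitError):
    """A configuration value violates its invariants."""


class SimulationError(PioneerKitError):
    """The synthetic-data generator could not satisfy its constraints."""


class SamplingError(PioneerKitError):
    """Rejection sampling exhausted its budget."""


class NormalizationError(PioneerKitError):
    """Size factors cannot be computed (no gene positive in every sample)."""


class UsageError(PioneerKitError):
    """An operation was called with inconsistent arguments."""
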