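"""Exception hierarchy for pulsebeta."""


class PulseBetaError(Exception):
    """Base class for all pulsebeta errors."""


class FormatError(PulseBetaError):
    """Input file or record violates the expected structure (missing channel,
    non-monotonic or duplicated timestamps, ragged columns)."""


class DataError(PulseBetaError):
    """Structurally valid input with unusable content (long NaN runs,
    non-finite pressure samples)."""


class ConfigError(PulseBetaError):
    """Invalid configuration value or inconsistent configuration."""


class SegmentationError(PulseBetaError):
    """R-peak detection or beat partitioning failed."""


class SimulationError(PulseBetaError):
    """Forward simulation failed (exponent overflow, schedule mismatch)."""


class EstimationError(PulseBetaError):
    """Per-beat parameter estimation failed (rank deficiency, empty mask).

    ``estimate_record`` catches this per beat and flags the beat invalid
    instead of aborting the record.
    """


class FitError(PulseBetaError):
    """Nonlinear sigmoid fit failed to converge from every start."""


class NormalizationError(PulseBetaError):
    """Baseline normalization impossible (no accepted beat in baseline)."""
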