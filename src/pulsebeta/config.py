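"""Pipeline configuration: a single YAML-loadable block with defaults.

Every default that the pipeline applies is echoed into the run log so a
run is auditable from its outputs alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .estimate import DerivativeSpec, EstimationConfig
from .io import DEFAULT_CHANNELS, BaselineWindow


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings.

    Either ``record`` (a waveform CSV path) or ``synth`` (keyword
    arguments for :func:`pulsebeta.synth.synthesize_record`) must be
    given.  ``seed`` drives every stochastic step.
    """

    record: str | None = None
    synth: dict = field(default_factory=dict)
    channels: dict = field(default_factory=lambda: dict(DEFAULT_CHANNELS))
    fs: float | None = None
    gap_limit_ms: float = 20.0
    derivative_window_ms: float = 21.0
    derivative_polyorder: int = 3
    r2_gate: float = 0.9
    min_mask_samples: int = 30
    mean_bp_scope: str = "beat"
    baseline_start: float = 222.0
    baseline_end: float = 246.0
    fit_variant: str = "stimulus"
    schedule: str = "default"
    seed: int = 0
    outdir: str = "pulsebeta_out"

    def __post_init__(self) -> None:
        if self.record is None and not self.synth:
            # an empty synth dict still means "synthesize with defaults"
            self.synth = {}
        if self.fit_variant not in ("stimulus", "none"):
            raise ConfigError(f"unsupported fit_variant {self.fit_variant!r}")
        if not self.baseline_start < self.baseline_end:
            raise ConfigError("baseline_start must precede baseline_end")

    @property
    def baseline(self) -> BaselineWindow:
        return BaselineWindow(self.baseline_start, self.baseline_end)

    def estimation(self) -> EstimationConfig:
        return EstimationConfig(
            derivative=DerivativeSpec(window_ms=self.derivative_window_ms,
                                      polyorder=self.derivative_polyorder),
            r2_gate=self.r2_gate,
            min_mask_samples=self.min_mask_samples,
            mean_bp_scope=self.mean_bp_scope,
        )

    def as_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"configuration file {path} must hold a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.as_dict(), sort_keys=False))
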