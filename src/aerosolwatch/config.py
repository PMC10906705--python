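"""Analysis configuration shared across pipeline stages."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError, ParameterError


@dataclass
class AnalysisConfig:
    """Tunable parameters of the particle-count analyses.

    Attributes
    ----------
    cutoff_um
        Diameter separating aerosols (<= cutoff) from droplets (> cutoff).
    kernel_samples
        Running-median window for background subtraction, in samples
        (odd).  11 samples at 7 s sampling span ~77 s: long relative to
        the seconds-scale transients, short relative to room drift.
    reference_window_min
        Length of the pre-procedure reference window, minutes.
    target_duration_min
        Duration all procedure totals are normalised to, minutes.
    pseudocount
        Added to counts before log transforms so zeros are representable;
        applied identically to every group being compared.
    filter_before_aggregation
        If True, the median filter runs per channel before the size
        fractions are summed; by default it runs on the aggregated
        fractions.
    event_window_s
        Window summed after an annotated event (three 7-s intervals by
        default: events last seconds but counter averaging smears them).
    baseline_window_s
        Window before the event whose per-interval median provides the
        local baseline expectation.
    n_null_events
        Null-reference windows sampled per procedure.
    min_gap_s
        Minimum separation of a null window from any annotated event and
        from other null windows.
    n_boot
        Bootstrap resamples for event ratio inference (>= 1000).
    ratio_statistic
        Per-group summary bootstrapped for event fold changes:
        ``mean_positive`` (default), ``median_positive`` or ``mean``.
    ratio_floor
        Lower clip for a group summary so ratios stay finite.
    """

    cutoff_um: float = 5.0
    kernel_samples: int = 11
    reference_window_min: float = 5.0
    target_duration_min: float = 20.0
    pseudocount: float = 1.0
    filter_before_aggregation: bool = False
    event_window_s: float = 21.0
    baseline_window_s: float = 70.0
    n_null_events: int = 3
    min_gap_s: float = 60.0
    n_boot: int = 10_000
    ratio_statistic: str = "mean_positive"
    ratio_floor: float = 1e-9

    def __post_init__(self):
        if self.kernel_samples < 3 or self.kernel_samples % 2 == 0:
            raise ParameterError("kernel_samples must be an odd integer >= 3")
        if self.cutoff_um <= 0:
            raise ConfigurationError("cutoff_um must be positive")
        if self.target_duration_min <= 0 or self.reference_window_min <= 0:
            raise ConfigurationError("window durations must be positive")
        if self.ratio_statistic not in ("mean_positive", "median_positive", "mean"):
            raise ConfigurationError(
                f"unknown ratio_statistic {self.ratio_statistic!r}"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(payload)
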