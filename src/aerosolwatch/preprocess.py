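"""Size-fraction aggregation, window extraction and background subtraction.

Room particle background varies slowly compared with the seconds-scale
transients produced by procedure events.  A running median tracks that
background; subtracting it leaves sharp increases ("spikes") that the
downstream analyses attribute to procedure activity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, ParameterError, ValidationError, WindowError
from .io import AggregateSeries, ParticleFrame, ProcedureRecord

__all__ = [
    "WindowSummary",
    "ReferenceWindow",
    "aggregate_size_fractions",
    "normalize_to_duration",
    "reference_window",
    "running_median",
    "median_filter_subtract",
    "window_slice",
    "window_counts",
]


@dataclass
class WindowSummary:
    """Counts in a time window, with their 20-minute-equivalent rescaling."""

    start_s: float
    end_s: float
    duration_min: float
    total_counts: float
    normalized_counts: float


@dataclass
class ReferenceWindow:
    """Bounds of the pre-procedure reference window.

    ``contaminated`` flags annotated activity inside the window, which
    disqualifies it as a no-activity baseline.
    """

    start_s: float
    end_s: float
    contaminated: bool = False

    @property
    def duration_min(self) -> float:
        return (self.end_s - self.start_s) / 60.0


def aggregate_size_fractions(frame: ParticleFrame, cutoff_um: float = 5.0) -> AggregateSeries:
    """Sum channels into aerosol (upper <= cutoff) and droplet (lower >= cutoff) totals.

    Every channel must lie entirely on one side of the cutoff, so the two
    fractions partition the channels and conserve row sums.
    """
    aerosol_cols, droplet_cols = [], []
    for j, ch in enumerate(frame.channels):
        if ch.upper_um <= cutoff_um:
            aerosol_cols.append(j)
        elif ch.lower_um >= cutoff_um:
            droplet_cols.append(j)
        else:
            raise ConfigurationError(
                f"channel [{ch.lower_um},{ch.upper_um}] um straddles the "
                f"{cutoff_um} um cutoff"
            )
    return AggregateSeries(
        timestamps=frame.timestamps,
        aerosol_counts=frame.counts[:, aerosol_cols].sum(axis=1),
        droplet_counts=frame.counts[:, droplet_cols].sum(axis=1),
        sample_period_s=frame.sample_period_s,
    )


def normalize_to_duration(total, duration_min: float, target_min: float = 20.0):
    """Rescale a count total to its ``target_min``-minute equivalent."""
    if duration_min <= 0:
        raise ValidationError(f"duration_min must be positive, got {duration_min}")
    if target_min <= 0:
        raise ValidationError(f"target_min must be positive, got {target_min}")
    return total * (target_min / duration_min)


def reference_window(record: ProcedureRecord, length_min: float = 5.0) -> ReferenceWindow:
    """Locate the pre-procedure reference window ``[start - L, start)``.

    Raises :class:`WindowError` if the recording does not start at least
    ``length_min`` minutes before the procedure; flags the window as
    contaminated if any annotated event falls inside it.
    """
    length_s = 60.0 * length_min
    if record.procedure_start_s < length_s:
        raise WindowError(
            f"only {record.procedure_start_s / 60.0:.1f} min of recording before "
            f"the procedure; {length_min:g} min required"
        )
    start = record.procedure_start_s - length_s
    end = record.procedure_start_s
    contaminated = any(start <= a.time_s < end for a in record.annotations)
    return ReferenceWindow(start_s=start, end_s=end, contaminated=contaminated)


def running_median(series: np.ndarray, kernel_samples: int) -> np.ndarray:
    """Sliding median with shrinking (truncated) windows at the edges.

    At index ``i`` the window is ``series[max(0, i-h) : i+h+1]`` with
    ``h = kernel_samples // 2``, so no values outside the recording are
    fabricated.
    """
    series = np.asarray(series, dtype=float)
    n = series.size
    if kernel_samples % 2 == 0 or kernel_samples < 3:
        raise ParameterError(f"kernel_samples must be odd and >= 3, got {kernel_samples}")
    if kernel_samples > n:
        raise ParameterError(
            f"kernel_samples={kernel_samples} exceeds series length {n}"
        )
    h = kernel_samples // 2
    out = np.empty(n)
    if n >= kernel_samples:
        windows = np.lib.stride_tricks.sliding_window_view(series, kernel_samples)
        out[h : n - h] = np.median(windows, axis=1)
    for i in range(min(h, n)):
        out[i] = np.median(series[: i + h + 1])
    for i in range(max(h, n - h), n):
        out[i] = np.median(series[i - h :])
    return out


def median_filter_subtract(series, kernel_samples: int = 11):
    """Subtract the running-median background from a count series.

    Returns ``(residual, spikes)`` where ``residual = series - running
    median`` (signed, kept for the mixture model downstream) and
    ``spikes = max(residual, 0)`` isolates the sharp increases.
    """
    series = np.asarray(series, dtype=float)
    residual = series - running_median(series, kernel_samples)
    spikes = np.maximum(residual, 0.0)
    return residual, spikes


def window_slice(timestamps: np.ndarray, sample_period_s: float, start_s: float, end_s: float):
    """Boolean mask of intervals whose start lies in ``[start_s, end_s)``."""
    timestamps = np.asarray(timestamps, dtype=float)
    return (timestamps >= start_s) & (timestamps < end_s)


def window_counts(
    series: AggregateSeries,
    fraction: str,
    start_s: float,
    end_s: float,
    values: np.ndarray | None = None,
    target_min: float = 20.0,
) -> WindowSummary:
    """Total counts of one size fraction over ``[start_s, end_s)``.

    ``values`` substitutes an alternative per-interval series (e.g. the
    spike series) aligned with ``series.timestamps``.
    """
    if end_s <= start_s:
        raise WindowError(f"empty window [{start_s}, {end_s})")
    mask = window_slice(series.timestamps, series.sample_period_s, start_s, end_s)
    if not np.any(mask):
        raise WindowError(f"no samples in window [{start_s}, {end_s})")
    data = series.fraction(fraction) if values is None else np.asarray(values)
    duration_min = (end_s - start_s) / 60.0
    total = float(data[mask].sum())
    return WindowSummary(
        start_s=start_s,
        end_s=end_s,
        duration_min=duration_min,
        total_counts=total,
        normalized_counts=float(normalize_to_duration(total, duration_min, target_min)),
    )
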