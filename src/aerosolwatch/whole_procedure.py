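"""Whole-procedure comparisons under the log-normal count model.

Respiratory particle production is well described by log-normal counts,
so fold changes between groups are estimated as geometric-mean ratios:
a two-sample Welch t-test on log-transformed 20-minute-equivalent counts
for arm-vs-arm comparisons, and a paired t-test on within-patient log
differences for procedure-vs-reference comparisons.  Confidence
intervals are t intervals on the log scale, exponentiated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .config import AnalysisConfig
from .errors import InferenceError, ValidationError, WindowError
from .io import AggregateSeries, ProcedureRecord
from .preprocess import (
    median_filter_subtract,
    reference_window,
    window_counts,
)

__all__ = [
    "RatioEstimate",
    "ProcedureSummary",
    "summarize_procedure",
    "log_ratio_test",
    "compare_arms",
    "procedure_vs_reference",
]

FRACTIONS = ("aerosol", "droplet")
VARIANTS = ("raw", "spike")


@dataclass
class RatioEstimate:
    """A fold change with its 95% CI, two-sided p-value and group sizes."""

    ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n_a: int
    n_b: int
    method: str
    comparison: str = ""
    fraction: str = ""
    variant: str = ""
    flags: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not (self.ci_low <= self.ratio <= self.ci_high):
            raise ValidationError(
                f"CI [{self.ci_low:g}, {self.ci_high:g}] does not bracket the "
                f"ratio {self.ratio:g}"
            )
        if not (0 < self.p_value <= 1):
            raise ValidationError(f"p-value {self.p_value} outside (0, 1]")


@dataclass
class ProcedureSummary:
    """20-minute-equivalent counts for one procedure, per fraction and variant.

    ``procedure`` and ``reference`` map ``(fraction, variant)`` to
    normalised counts; reference entries are absent when no clean
    pre-procedure window exists.
    """

    procedure_id: str
    arm: str
    used_throat_spray: bool
    procedure: dict
    reference: dict
    reference_valid: bool
    flags: list[str] = field(default_factory=list)


def summarize_procedure(
    series: AggregateSeries,
    record: ProcedureRecord,
    config: AnalysisConfig | None = None,
) -> ProcedureSummary:
    """Raw and spike-filtered 20-min-equivalent counts for procedure and reference windows.

    The spike variant subtracts the running-median background from each
    size fraction before summing, isolating sharp transient increases.
    """
    config = config or AnalysisConfig()
    flags: list[str] = []
    try:
        ref = reference_window(record, config.reference_window_min)
        reference_valid = not ref.contaminated
        if ref.contaminated:
            flags.append("reference_window_contaminated")
    except WindowError as exc:
        ref = None
        reference_valid = False
        flags.append(f"no_reference_window: {exc}")

    spikes = {}
    for fraction in FRACTIONS:
        _, spikes[fraction] = median_filter_subtract(
            series.fraction(fraction), config.kernel_samples
        )

    procedure, reference = {}, {}
    for fraction in FRACTIONS:
        for variant in VARIANTS:
            values = None if variant == "raw" else spikes[fraction]
            summary = window_counts(
                series,
                fraction,
                record.procedure_start_s,
                record.procedure_end_s,
                values=values,
                target_min=config.target_duration_min,
            )
            procedure[(fraction, variant)] = summary.normalized_counts
            if reference_valid:
                ref_summary = window_counts(
                    series,
                    fraction,
                    ref.start_s,
                    ref.end_s,
                    values=values,
                    target_min=config.target_duration_min,
                )
                reference[(fraction, variant)] = ref_summary.normalized_counts

    return ProcedureSummary(
        procedure_id=record.procedure_id,
        arm=record.arm,
        used_throat_spray=record.used_throat_spray,
        procedure=procedure,
        reference=reference,
        reference_valid=reference_valid,
        flags=flags,
    )


def _welch_on_logs(log_a: np.ndarray, log_b: np.ndarray):
    """Welch statistic, Satterthwaite df, SE of the mean log difference."""
    na, nb = log_a.size, log_b.size
    va, vb = log_a.var(ddof=1), log_b.var(ddof=1)
    se2 = va / na + vb / nb
    diff = log_a.mean() - log_b.mean()
    if se2 == 0:
        return diff, 0.0, np.inf, 0.0
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    t = diff / np.sqrt(se2)
    return diff, t, df, np.sqrt(se2)


def log_ratio_test(
    group_a,
    group_b,
    pseudocount: float = 1.0,
    comparison: str = "",
    fraction: str = "",
    variant: str = "",
) -> RatioEstimate:
    """Geometric-mean fold change of group a over group b with Welch inference.

    Counts are shifted by ``pseudocount`` (identically in both groups) and
    log-transformed; the ratio is ``exp(mean(log a) - mean(log b))``, the
    CI the exponentiated 95% Welch t interval, the p-value two-sided.
    """
    a = np.asarray(group_a, dtype=float) + pseudocount
    b = np.asarray(group_b, dtype=float) + pseudocount
    if a.size < 2 or b.size < 2:
        raise InferenceError(
            f"each group needs >= 2 values, got {a.size} and {b.size}"
        )
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValidationError("values + pseudocount must be positive for the log transform")
    log_a, log_b = np.log(a), np.log(b)
    diff, t, df, se = _welch_on_logs(log_a, log_b)
    if se == 0:
        # both groups constant: ratio exactly known, no sampling variability
        p = 1.0 if diff == 0 else np.finfo(float).tiny
        half = 0.0
    else:
        p = 2.0 * stats.t.sf(abs(t), df)
        half = stats.t.ppf(0.975, df) * se
    return RatioEstimate(
        ratio=float(np.exp(diff)),
        ci_low=float(np.exp(diff - half)),
        ci_high=float(np.exp(diff + half)),
        p_value=float(min(max(p, np.finfo(float).tiny), 1.0)),
        n_a=int(a.size),
        n_b=int(b.size),
        method="log_t",
        comparison=comparison,
        fraction=fraction,
        variant=variant,
    )


def _arm_values(summaries, arm, fraction, variant, exclude_throat_spray):
    vals = []
    for s in summaries:
        if s.arm != arm:
            continue
        if exclude_throat_spray and s.used_throat_spray:
            continue
        vals.append(s.procedure[(fraction, variant)])
    return np.asarray(vals, dtype=float)


def compare_arms(
    summaries,
    fraction: str = "aerosol",
    variant: str = "raw",
    arm_a: str = "EGD",
    arm_b: str = "Cytosponge",
    exclude_throat_spray_from: str | None = None,
    pseudocount: float = 1.0,
) -> RatioEstimate:
    """Fold change of arm_a over arm_b in 20-min-equivalent counts.

    ``exclude_throat_spray_from`` drops procedures that used anaesthetic
    throat spray from the named arm (e.g. restrict the Cytosponge group
    to spray-free procedures) before testing.
    """
    a = _arm_values(summaries, arm_a, fraction, variant, exclude_throat_spray_from == arm_a)
    b = _arm_values(summaries, arm_b, fraction, variant, exclude_throat_spray_from == arm_b)
    for arm, vals in ((arm_a, a), (arm_b, b)):
        if vals.size < 2:
            filt = (
                f" after excluding throat-spray procedures"
                if exclude_throat_spray_from == arm
                else ""
            )
            raise InferenceError(
                f"arm {arm!r} has {vals.size} procedures{filt}; >= 2 required"
            )
    name = f"{arm_a}_vs_{arm_b}"
    if exclude_throat_spray_from:
        name += f"_no_spray_{exclude_throat_spray_from}"
    return log_ratio_test(
        a, b, pseudocount=pseudocount, comparison=name, fraction=fraction, variant=variant
    )


def procedure_vs_reference(
    summaries,
    fraction: str = "aerosol",
    variant: str = "raw",
    arm: str | None = None,
    pseudocount: float = 1.0,
) -> RatioEstimate:
    """Paired fold change of procedure windows over their own reference windows.

    Uses a paired t-test on ``log(procedure + pc) - log(reference + pc)``
    over procedures with a clean pre-procedure window; the ratio is the
    exponentiated mean paired log difference.
    """
    diffs = []
    n_total = 0
    for s in summaries:
        if arm is not None and s.arm != arm:
            continue
        n_total += 1
        if not s.reference_valid:
            continue
        p = s.procedure[(fraction, variant)] + pseudocount
        r = s.reference[(fraction, variant)] + pseudocount
        if p <= 0 or r <= 0:
            raise ValidationError("non-positive value after pseudocount shift")
        diffs.append(np.log(p) - np.log(r))
    diffs = np.asarray(diffs)
    if diffs.size < 2:
        raise InferenceError(
            f"{diffs.size} of {n_total} procedures have a valid reference window; "
            "paired inference needs >= 2"
        )
    mean = diffs.mean()
    se = diffs.std(ddof=1) / np.sqrt(diffs.size)
    df = diffs.size - 1
    if se == 0:
        p_value = 1.0 if mean == 0 else np.finfo(float).tiny
        half = 0.0
    else:
        t = mean / se
        p_value = 2.0 * stats.t.sf(abs(t), df)
        half = stats.t.ppf(0.975, df) * se
    name = "procedure_vs_reference" + (f"_{arm}" if arm else "")
    return RatioEstimate(
        ratio=float(np.exp(mean)),
        ci_low=float(np.exp(mean - half)),
        ci_high=float(np.exp(mean + half)),
        p_value=float(min(max(p_value, np.finfo(float).tiny), 1.0)),
        n_a=int(diffs.size),
        n_b=int(diffs.size),
        method="paired_log_t",
        comparison=name,
        fraction=fraction,
        variant=variant,
    )
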