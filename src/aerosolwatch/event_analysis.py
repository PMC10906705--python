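"""Event-based excess-particle quantification.

Each annotated event (sponge removal, throat spray, burp, ...) is scored
by the particle counts in a short window after the event minus the local
baseline expectation, estimated as the per-interval median of a window
immediately before the event.  Because the subtraction can go negative,
the excess distribution is modelled as a log-normal (genuine event
production) plus normal (subtraction noise) mixture, and fold changes
between event classes are tested with a percentile bootstrap on the
ratio of group summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import (
    DegenerateFitError,
    ExtractionError,
    InferenceError,
    ParameterError,
    SamplingError,
)
from .io import AggregateSeries, EventAnnotation
from .whole_procedure import RatioEstimate

__all__ = [
    "EventExcess",
    "MixtureFit",
    "extract_event_excess",
    "sample_null_events",
    "fit_lognormal_normal_mixture",
    "bootstrap_ratio",
    "event_vs_null",
]

FRACTIONS = ("aerosol", "droplet")


@dataclass
class EventExcess:
    """Background-subtracted excess counts for one event, per size fraction.

    ``excess`` maps fraction name to a signed count: event-window total
    minus baseline-rate expectation.  Negative values are retained; they
    arise when the local baseline overestimates the event window.
    """

    procedure_id: str
    label: str
    time_s: float
    excess: dict

    def value(self, fraction: str) -> float:
        return self.excess[fraction]


@dataclass
class MixtureFit:
    """Maximum-likelihood fit of a log-normal + normal mixture."""

    weight_lognormal: float
    mu_log: float
    sigma_log: float
    mu_norm: float
    sigma_norm: float
    loglik: float
    converged: bool
    n_iter: int = 0
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))


def extract_event_excess(
    series: AggregateSeries,
    event: EventAnnotation,
    event_window_s: float = 21.0,
    baseline_window_s: float = 70.0,
) -> EventExcess:
    """Excess counts in ``[t, t+event_window)`` over the local baseline.

    The baseline expectation is the median per-interval count over
    ``[t - baseline_window, t)`` multiplied by the number of event
    intervals, computed per size fraction.  Adding a constant to the
    whole series leaves the excess unchanged.
    """
    t = event.time_s
    ts = series.timestamps
    period = series.sample_period_s
    t0 = ts[0] if ts.size else 0.0
    if t - baseline_window_s < t0:
        raise ExtractionError(
            f"event at {t:g}s needs a {baseline_window_s:g}s baseline window but "
            f"the recording starts at {t0:g}s"
        )
    event_mask = (ts >= t) & (ts < t + event_window_s)
    base_mask = (ts >= t - baseline_window_s) & (ts < t)
    if not event_mask.any():
        raise ExtractionError(f"no samples in event window starting at {t:g}s")
    if not base_mask.any():
        raise ExtractionError(f"no samples in baseline window before {t:g}s")
    n_event = int(event_mask.sum())
    excess = {}
    for fraction in FRACTIONS:
        values = series.fraction(fraction)
        baseline_rate = float(np.median(values[base_mask]))
        excess[fraction] = float(values[event_mask].sum()) - baseline_rate * n_event
    return EventExcess(procedure_id="", label=event.label, time_s=t, excess=excess)


def sample_null_events(
    series: AggregateSeries,
    annotations,
    n_events: int,
    min_gap_s: float = 60.0,
    rng_seed: int | np.random.Generator = 0,
    event_window_s: float = 21.0,
    baseline_window_s: float = 70.0,
    within: tuple[float, float] | None = None,
    allow_fewer: bool = False,
) -> list[EventExcess]:
    """Draw ``n_events`` null-reference windows clear of annotated activity.

    Candidate start times are interval starts at least ``min_gap_s`` from
    every annotation (measured to the nearest edge of the null window),
    with room for the baseline window before and the event window after.
    Accepted windows are pairwise >= ``min_gap_s`` apart.  Reproducible
    under ``rng_seed``.  With ``allow_fewer`` the available windows are
    returned (at least one) instead of raising when capacity falls short.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    ts = series.timestamps
    period = series.sample_period_s
    lo = (ts[0] + baseline_window_s) if within is None else max(ts[0] + baseline_window_s, within[0])
    hi = (ts[-1] + period - event_window_s) if within is None else min(
        ts[-1] + period - event_window_s, within[1] - event_window_s
    )
    eligible = ts[(ts >= lo) & (ts <= hi)]
    ann_times = np.array([a.time_s for a in annotations], dtype=float)
    if ann_times.size:
        # distance from the null window [t, t+w) to each annotation
        dist = np.minimum.reduce(
            [np.abs(eligible[:, None] - ann_times[None, :]),
             np.abs(eligible[:, None] + event_window_s - ann_times[None, :])]
        )
        inside = (ann_times[None, :] >= eligible[:, None]) & (
            ann_times[None, :] < eligible[:, None] + event_window_s
        )
        clear = np.all((dist >= min_gap_s) & ~inside, axis=1)
        eligible = eligible[clear]
    if eligible.size == 0:
        raise SamplingError("no annotation-free stretches available for null events")
    order = rng.permutation(eligible.size)
    chosen: list[float] = []
    for idx in order:
        t = float(eligible[idx])
        if all(abs(t - c) >= min_gap_s for c in chosen):
            chosen.append(t)
            if len(chosen) == n_events:
                break
    if len(chosen) < n_events and not allow_fewer:
        raise SamplingError(
            f"only {len(chosen)} null windows satisfy the {min_gap_s:g}s spacing; "
            f"{n_events} requested"
        )
    out = []
    for t in sorted(chosen):
        ev = extract_event_excess(
            series,
            EventAnnotation(time_s=t, label="null_reference"),
            event_window_s=event_window_s,
            baseline_window_s=baseline_window_s,
        )
        out.append(ev)
    return out


# ---------------------------------------------------------------------------
# mixture model


def _mixture_loglik(x, w, mu_l, s_l, mu_n, s_n):
    dens = (1.0 - w) * stats.norm.pdf(x, mu_n, s_n)
    pos = x > 0
    dens = dens.copy()
    dens[pos] += w * stats.lognorm.pdf(x[pos], s=s_l, scale=np.exp(mu_l))
    return float(np.sum(np.log(np.maximum(dens, 1e-300))))


_SIGMA_FLOOR = 1e-4


def _em_fit(x, w0, max_iter=500, tol=1e-9):
    pos = x > 0
    logx = np.where(pos, np.log(np.where(pos, x, 1.0)), 0.0)
    mu_l = logx[pos].mean()
    s_l = max(logx[pos].std(), _SIGMA_FLOOR)
    mu_n = x.mean()
    s_n = max(x.std(), _SIGMA_FLOOR)
    w = w0
    trace = []
    converged = False
    for it in range(max_iter):
        # E-step: responsibility of the log-normal component
        dens_n = (1.0 - w) * stats.norm.pdf(x, mu_n, s_n)
        dens_l = np.zeros_like(x)
        dens_l[pos] = w * stats.lognorm.pdf(x[pos], s=s_l, scale=np.exp(mu_l))
        total = np.maximum(dens_l + dens_n, 1e-300)
        trace.append(float(np.sum(np.log(total))))
        r = dens_l / total
        # M-step
        w = float(r.mean())
        if r[pos].sum() > 1e-12:
            wl = r[pos]
            mu_l = float(np.average(logx[pos], weights=wl))
            s_l = float(
                max(np.sqrt(np.average((logx[pos] - mu_l) ** 2, weights=wl)), _SIGMA_FLOOR)
            )
        wn = 1.0 - r
        if wn.sum() > 1e-12:
            mu_n = float(np.average(x, weights=wn))
            s_n = float(max(np.sqrt(np.average((x - mu_n) ** 2, weights=wn)), _SIGMA_FLOOR))
        if it > 0 and abs(trace[-1] - trace[-2]) < tol * (1.0 + abs(trace[-2])):
            converged = True
            break
    ll = _mixture_loglik(x, w, mu_l, s_l, mu_n, s_n)
    trace.append(ll)
    return MixtureFit(
        weight_lognormal=w,
        mu_log=mu_l,
        sigma_log=s_l,
        mu_norm=mu_n,
        sigma_norm=s_n,
        loglik=ll,
        converged=converged,
        n_iter=len(trace) - 1,
        loglik_trace=np.asarray(trace),
    )


def fit_lognormal_normal_mixture(samples, min_samples: int = 8) -> MixtureFit:
    """Fit ``w * LogNormal(mu_log, sigma_log) + (1-w) * Normal(mu_norm, sigma_norm)``.

    Expectation-maximisation with multiple starting weights; the fit with
    the best log-likelihood is returned.  Samples <= 0 necessarily belong
    to the normal component.  Requires ``min_samples`` values and at
    least one positive sample; otherwise a :class:`DegenerateFitError`
    carrying the normal-only fit is raised.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < min_samples:
        raise ParameterError(f"mixture fit needs >= {min_samples} samples, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ParameterError("mixture fit requires finite samples")
    if not np.any(x > 0):
        mu_n, s_n = float(x.mean()), float(max(x.std(), _SIGMA_FLOOR))
        fit = MixtureFit(
            weight_lognormal=0.0,
            mu_log=np.nan,
            sigma_log=np.nan,
            mu_norm=mu_n,
            sigma_norm=s_n,
            loglik=float(np.sum(stats.norm.logpdf(x, mu_n, s_n))),
            converged=False,
        )
        raise DegenerateFitError("all samples non-positive: log-normal weight -> 0", fit)
    best = None
    for w0 in (0.05, 0.3, 0.6, 0.9):
        fit = _em_fit(x, w0)
        if best is None or fit.loglik > best.loglik:
            best = fit
    return best


# ---------------------------------------------------------------------------
# bootstrap inference


def _group_summary(values: np.ndarray, statistic: str, floor: float, axis=None):
    if statistic == "mean_positive":
        s = np.maximum(values, 0.0).mean(axis=axis)
    elif statistic == "median_positive":
        s = np.median(np.maximum(values, 0.0), axis=axis)
    elif statistic == "mean":
        s = values.mean(axis=axis)
    else:
        raise ParameterError(f"unknown ratio statistic {statistic!r}")
    return np.maximum(s, floor)


def bootstrap_ratio(
    events_a,
    events_b,
    fraction: str = "aerosol",
    n_boot: int = 10_000,
    rng_seed: int | np.random.Generator = 0,
    statistic: str = "mean_positive",
    floor: float = 1e-9,
    comparison: str = "",
) -> RatioEstimate:
    """Percentile-bootstrap fold change of event group a over group b.

    The per-group summary (mean of positive parts by default, since
    excesses can be negative) is recomputed over ``n_boot`` resamples of
    each event list; the CI is the percentile interval and the p-value
    the two-sided proportion of bootstrap ratios crossing 1 with a
    ``+1/(n_boot+1)`` continuity correction.
    """
    if n_boot < 1000:
        raise ParameterError(f"n_boot must be >= 1000, got {n_boot}")
    a = np.asarray([e.value(fraction) for e in events_a], dtype=float)
    b = np.asarray([e.value(fraction) for e in events_b], dtype=float)
    if a.size == 0 or b.size == 0:
        raise InferenceError("both event lists must be non-empty")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    flags = []
    sa = float(_group_summary(a, statistic, floor))
    sb = float(_group_summary(b, statistic, floor))
    if sb <= floor:
        flags.append("denominator_floored")
    if sa <= floor:
        flags.append("numerator_floored")
    ratio = sa / sb
    idx_a = rng.integers(0, a.size, size=(n_boot, a.size))
    idx_b = rng.integers(0, b.size, size=(n_boot, b.size))
    boot = _group_summary(a[idx_a], statistic, floor, axis=1) / _group_summary(
        b[idx_b], statistic, floor, axis=1
    )
    ci_low, ci_high = np.percentile(boot, [2.5, 97.5])
    below = int(np.sum(boot <= 1.0))
    above = int(np.sum(boot >= 1.0))
    p = 2.0 * min((below + 1) / (n_boot + 1), (above + 1) / (n_boot + 1))
    return RatioEstimate(
        ratio=ratio,
        ci_low=float(min(ci_low, ratio)),
        ci_high=float(max(ci_high, ratio)),
        p_value=float(min(p, 1.0)),
        n_a=int(a.size),
        n_b=int(b.size),
        method="bootstrap",
        comparison=comparison,
        fraction=fraction,
        flags=flags,
    )


def event_vs_null(
    events,
    nulls,
    fraction: str = "aerosol",
    n_boot: int = 10_000,
    rng_seed: int | np.random.Generator = 0,
    statistic: str = "mean_positive",
    floor: float = 1e-9,
) -> RatioEstimate:
    """Fold excess of an event class over sampled null-reference windows."""
    if not nulls:
        raise InferenceError("null-reference event list is empty")
    labels = {e.label for e in events}
    name = f"{'/'.join(sorted(labels)) or 'event'}_vs_null"
    return bootstrap_ratio(
        events,
        nulls,
        fraction=fraction,
        n_boot=n_boot,
        rng_seed=rng_seed,
        statistic=statistic,
        floor=floor,
        comparison=name,
    )
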