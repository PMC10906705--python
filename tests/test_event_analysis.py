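import numpy as np
import pytest

from aerosolwatch import (
    AggregateSeries,
    EventAnnotation,
    bootstrap_ratio,
    event_vs_null,
    extract_event_excess,
    fit_lognormal_normal_mixture,
    sample_null_events,
)
from aerosolwatch.errors import (
    DegenerateFitError,
    ExtractionError,
    InferenceError,
    ParameterError,
    SamplingError,
)
from aerosolwatch.event_analysis import EventExcess


def make_series(aerosol, droplet=None):
    aerosol = np.asarray(aerosol)
    droplet = np.zeros_like(aerosol) if droplet is None else np.asarray(droplet)
    return AggregateSeries(
        timestamps=np.arange(aerosol.size) * 7.0,
        aerosol_counts=aerosol,
        droplet_counts=droplet,
    )


def make_events(values, label="removal"):
    return [
        EventExcess(procedure_id=f"p{i}", label=label, time_s=0.0,
                    excess={"aerosol": float(v), "droplet": 0.0})
        for i, v in enumerate(values)
    ]


class TestExtractEventExcess:
    def test_constant_series_zero_excess(self):
        series = make_series(np.full(100, 7), np.full(100, 3))
        ev = extract_event_excess(series, EventAnnotation(time_s=350.0, label="burp"))
        assert ev.excess["aerosol"] == 0.0
        assert ev.excess["droplet"] == 0.0

    def test_spike_over_baseline_arithmetic(self):
        aerosol = np.full(60, 5)
        aerosol[30:33] = [5, 50, 5]  # event intervals sum 60, baseline 5/interval
        series = make_series(aerosol)
        ev = extract_event_excess(series, EventAnnotation(time_s=210.0, label="removal"))
        assert ev.excess["aerosol"] == 45.0

    def test_event_too_early_rejected(self):
        series = make_series(np.full(60, 5))
        with pytest.raises(ExtractionError, match="baseline"):
            extract_event_excess(series, EventAnnotation(time_s=35.0, label="burp"))

    def test_invariant_to_constant_shift(self, rng):
        base = rng.integers(0, 40, size=120)
        ev1 = extract_event_excess(make_series(base), EventAnnotation(400.0, "burp"))
        ev2 = extract_event_excess(make_series(base + 17), EventAnnotation(400.0, "burp"))
        assert ev1.excess["aerosol"] == pytest.approx(ev2.excess["aerosol"])


class TestSampleNullEvents:
    def test_spacing_and_count(self):
        series = make_series(np.full(400, 5))
        nulls = sample_null_events(series, [], 5, min_gap_s=60.0, rng_seed=3)
        assert len(nulls) == 5
        times = sorted(e.time_s for e in nulls)
        assert all(b - a >= 60.0 for a, b in zip(times, times[1:]))
        assert all(e.label == "null_reference" for e in nulls)

    def test_fully_annotated_recording_rejected(self):
        series = make_series(np.full(100, 5))
        anns = [EventAnnotation(float(t), "burp") for t in range(0, 700, 50)]
        with pytest.raises(SamplingError):
            sample_null_events(series, anns, 2, min_gap_s=60.0, rng_seed=0)

    def test_seed_reproducibility(self):
        series = make_series(np.full(400, 5))
        a = sample_null_events(series, [], 4, rng_seed=11)
        b = sample_null_events(series, [], 4, rng_seed=11)
        assert [e.time_s for e in a] == [e.time_s for e in b]

    def test_nulls_respect_annotation_gap(self):
        series = make_series(np.full(400, 5))
        anns = [EventAnnotation(1400.0, "removal")]
        nulls = sample_null_events(series, anns, 6, min_gap_s=60.0, rng_seed=5)
        for e in nulls:
            assert min(abs(e.time_s - 1400.0), abs(e.time_s + 21.0 - 1400.0)) >= 60.0


class TestMixtureFit:
    def test_recovers_pure_lognormal(self):
        rng = np.random.default_rng(42)
        fit = fit_lognormal_normal_mixture(rng.lognormal(2.0, 0.5, 500))
        assert fit.weight_lognormal >= 0.9
        assert fit.mu_log == pytest.approx(2.0, abs=0.15)
        assert fit.converged

    def test_recovers_pure_normal(self):
        rng = np.random.default_rng(43)
        fit = fit_lognormal_normal_mixture(rng.normal(0.0, 1.0, 500))
        assert fit.weight_lognormal <= 0.1

    def test_loglik_monotone_on_every_fit(self):
        rng = np.random.default_rng(44)
        for _ in range(10):
            x = np.concatenate(
                [rng.lognormal(2.5, 0.6, 80), rng.normal(0, 4, rng.integers(20, 60))]
            )
            fit = fit_lognormal_normal_mixture(x)
            assert np.all(np.diff(fit.loglik_trace) >= -1e-7)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ParameterError):
            fit_lognormal_normal_mixture([1.0] * 7)

    def test_all_negative_degenerate(self):
        with pytest.raises(DegenerateFitError) as exc:
            fit_lognormal_normal_mixture([-1.0, -2.0, -0.5, -3, -1, -2, -4, -1.5])
        assert exc.value.fit.weight_lognormal == 0.0


class TestBootstrapRatio:
    def test_self_comparison_is_null(self):
        events = make_events([10, 25, 3, 40, 8, 15, 30, 5, 12, 22])
        est = bootstrap_ratio(events, events, n_boot=2000, rng_seed=0)
        assert est.ratio == pytest.approx(1.0)
        assert est.p_value > 0.5

    def test_tenfold_separation_detected(self):
        rng = np.random.default_rng(1)
        detected = 0
        for seed in range(20):
            base = rng.lognormal(3, 0.4, 17)
            a = make_events(base * 10)
            b = make_events(base)
            est = bootstrap_ratio(a, b, n_boot=1000, rng_seed=seed)
            detected += est.p_value < 0.05
        assert detected >= 19

    def test_exchangeability_inverts_ratio(self):
        a = make_events([5, 60, 22, 11, 48, 7, 33])
        b = make_events([3, 9, 14, 2, 30, 11, 6])
        fwd = bootstrap_ratio(a, b, n_boot=1000, rng_seed=2)
        rev = bootstrap_ratio(b, a, n_boot=1000, rng_seed=2)
        assert rev.ratio == pytest.approx(1.0 / fwd.ratio, rel=1e-12)

    def test_small_n_boot_rejected(self):
        events = make_events([1, 2, 3])
        with pytest.raises(ParameterError):
            bootstrap_ratio(events, events, n_boot=10)

    def test_all_negative_denominator_floored(self):
        a = make_events([10, 20, 30, 40])
        b = make_events([-5, -2, -9, -1])
        est = bootstrap_ratio(a, b, n_boot=1000, rng_seed=0, floor=1e-9)
        assert "denominator_floored" in est.flags
        assert est.ratio > 1e9

    def test_empty_null_list_rejected(self):
        with pytest.raises(InferenceError):
            event_vs_null(make_events([1, 2]), [], n_boot=1000)

    def test_seed_reproducibility(self):
        a = make_events([5, 60, 22, 11, 48, 7, 33])
        b = make_events([3, 9, 14, 2, 30, 11, 6])
        r1 = bootstrap_ratio(a, b, n_boot=1000, rng_seed=9)
        r2 = bootstrap_ratio(a, b, n_boot=1000, rng_seed=9)
        assert (r1.ci_low, r1.ci_high, r1.p_value) == (r2.ci_low, r2.ci_high, r2.p_value)
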