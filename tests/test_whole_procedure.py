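import numpy as np
import pytest
from scipy import special

from aerosolwatch import (
    AggregateSeries,
    AnalysisConfig,
    RatioEstimate,
    compare_arms,
    log_ratio_test,
    procedure_vs_reference,
    summarize_procedure,
)
from aerosolwatch.errors import InferenceError, ValidationError
from aerosolwatch.preprocess import aggregate_size_fractions
from aerosolwatch.whole_procedure import ProcedureSummary
from conftest import make_record


def welch_oracle(a, b):
    """Closed-form Welch t on logs, p via the incomplete-beta identity."""
    la, lb = np.log(a), np.log(b)
    na, nb = len(a), len(b)
    va, vb = la.var(ddof=1), lb.var(ddof=1)
    se2 = va / na + vb / nb
    t = (la.mean() - lb.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = special.betainc(df / 2.0, 0.5, df / (df + t**2))
    return float(np.exp(la.mean() - lb.mean())), float(t), float(df), float(p)


def make_summary(pid, arm, aerosol_raw, spray=False, reference=None):
    proc = {(f, v): aerosol_raw for f in ("aerosol", "droplet") for v in ("raw", "spike")}
    ref = {}
    if reference is not None:
        ref = {(f, v): reference for f in ("aerosol", "droplet") for v in ("raw", "spike")}
    return ProcedureSummary(
        procedure_id=pid,
        arm=arm,
        used_throat_spray=spray,
        procedure=proc,
        reference=ref,
        reference_valid=reference is not None,
    )


class TestLogRatioTest:
    def test_identical_groups(self):
        est = log_ratio_test([10, 20, 40], [10, 20, 40])
        assert est.ratio == pytest.approx(1.0)
        assert est.p_value == pytest.approx(1.0)

    def test_exact_geometric_mean_ratio(self):
        est = log_ratio_test([20, 40, 80], [10, 20, 40], pseudocount=0.0)
        assert est.ratio == pytest.approx(2.0, rel=1e-12)

    def test_matches_welch_oracle_on_logs(self):
        a, b = [10.0, 20.0, 40.0], [11.0, 19.0, 42.0]
        est = log_ratio_test(a, b, pseudocount=1.0)
        ratio, _, _, p = welch_oracle(np.array(a) + 1.0, np.array(b) + 1.0)
        assert est.ratio == pytest.approx(ratio, rel=1e-10)
        assert est.p_value == pytest.approx(p, rel=1e-10)

    def test_small_group_rejected(self):
        with pytest.raises(InferenceError):
            log_ratio_test([10], [10, 20])

    def test_scale_equivariance(self, rng):
        a = rng.lognormal(3, 0.5, 12)
        b = rng.lognormal(3, 0.5, 9)
        base = log_ratio_test(a, b, pseudocount=0.0)
        one = log_ratio_test(a * 7.0, b, pseudocount=0.0)
        assert one.ratio == pytest.approx(7.0 * base.ratio, rel=1e-10)
        # rescaling both groups changes neither the ratio nor the p-value
        both = log_ratio_test(a * 7.0, b * 7.0, pseudocount=0.0)
        assert both.ratio == pytest.approx(base.ratio, rel=1e-10)
        assert both.p_value == pytest.approx(base.p_value, rel=1e-9)

    def test_exchangeability_inverts_ratio(self, rng):
        a = rng.lognormal(2, 0.8, 10)
        b = rng.lognormal(2.5, 0.4, 14)
        fwd = log_ratio_test(a, b, pseudocount=0.0)
        rev = log_ratio_test(b, a, pseudocount=0.0)
        assert rev.ratio == pytest.approx(1.0 / fwd.ratio, rel=1e-10)
        assert rev.ci_low == pytest.approx(1.0 / fwd.ci_high, rel=1e-9)
        assert rev.p_value == pytest.approx(fwd.p_value, rel=1e-10)

    def test_null_rejection_rate_calibrated(self, rng):
        # both groups log-normal with equal parameters: the Welch t on
        # logs is exact, so rejections at 0.05 stay near 5%
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            a = rng.lognormal(5, 0.7, 10)
            b = rng.lognormal(5, 0.7, 10)
            if log_ratio_test(a, b, pseudocount=0.0).p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_sim <= 0.07


class TestSummarizeProcedure:
    def test_constant_series_arithmetic(self):
        n = 200
        series = AggregateSeries(
            timestamps=np.arange(n) * 7.0,
            aerosol_counts=np.full(n, 10),
            droplet_counts=np.zeros(n, dtype=int),
        )
        rec = make_record(start=420.0, end=1020.0)  # 10-minute procedure
        s = summarize_procedure(series, rec, AnalysisConfig())
        # 86 interval starts in [420, 1020) -> 860 counts -> x2 for 20 min
        assert s.procedure[("aerosol", "raw")] == pytest.approx(1720.0)
        # constant series: the running median removes everything
        assert s.procedure[("aerosol", "spike")] == pytest.approx(0.0)
        assert s.reference_valid
        # reference window [120, 420): interval starts 126..413 -> 42
        # intervals x10 counts, x4 for the 20-minute equivalent
        assert s.reference[("aerosol", "raw")] == pytest.approx(1680.0)

    def test_spike_never_exceeds_raw(self, small_study):
        cfg = AnalysisConfig()
        for frame, rec in small_study:
            s = summarize_procedure(aggregate_size_fractions(frame), rec, cfg)
            for f in ("aerosol", "droplet"):
                assert s.procedure[(f, "spike")] <= s.procedure[(f, "raw")] + 1e-9


class TestCompareArms:
    def test_exact_doubling(self):
        vals = [100.0, 220.0, 150.0, 400.0]
        summaries = [make_summary(f"a{i}", "EGD", v * 2) for i, v in enumerate(vals)]
        summaries += [make_summary(f"b{i}", "Cytosponge", v) for i, v in enumerate(vals)]
        est = compare_arms(summaries, "aerosol", "raw", pseudocount=0.0)
        assert est.ratio == pytest.approx(2.0, rel=1e-12)

    def test_single_procedure_arm_rejected(self):
        summaries = [
            make_summary("a", "EGD", 10.0),
            make_summary("b", "EGD", 12.0),
            make_summary("c", "Cytosponge", 11.0),
        ]
        with pytest.raises(InferenceError, match="Cytosponge"):
            compare_arms(summaries, "aerosol", "raw")

    def test_throat_spray_exclusion_names_filter(self):
        summaries = [make_summary(f"a{i}", "EGD", 10.0 + i, spray=True) for i in range(3)]
        summaries += [
            make_summary(f"b{i}", "Cytosponge", 10.0, spray=True) for i in range(3)
        ]
        with pytest.raises(InferenceError, match="throat-spray"):
            compare_arms(summaries, "aerosol", "raw", exclude_throat_spray_from="Cytosponge")


class TestProcedureVsReference:
    def test_identical_windows_give_unit_ratio(self):
        summaries = [
            make_summary(f"p{i}", "Cytosponge", 50.0, reference=50.0) for i in range(5)
        ]
        est = procedure_vs_reference(summaries, "aerosol", "raw")
        assert est.ratio == pytest.approx(1.0)
        assert est.p_value == pytest.approx(1.0)

    def test_exact_tripling(self):
        vals = [30.0, 60.0, 45.0, 90.0]
        summaries = [
            make_summary(f"p{i}", "Cytosponge", v * 3, reference=v)
            for i, v in enumerate(vals)
        ]
        est = procedure_vs_reference(summaries, "aerosol", "raw", pseudocount=0.0)
        assert est.ratio == pytest.approx(3.0, rel=1e-12)

    def test_no_valid_pairs_rejected(self):
        summaries = [make_summary(f"p{i}", "Cytosponge", 10.0) for i in range(4)]
        with pytest.raises(InferenceError):
            procedure_vs_reference(summaries, "aerosol", "raw")


def test_ratio_estimate_invariants_enforced():
    with pytest.raises(ValidationError):
        RatioEstimate(
            ratio=2.0, ci_low=2.5, ci_high=3.0, p_value=0.5, n_a=3, n_b=3, method="log_t"
        )
    with pytest.raises(ValidationError):
        RatioEstimate(
            ratio=2.0, ci_low=1.0, ci_high=3.0, p_value=0.0, n_a=3, n_b=3, method="log_t"
        )
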