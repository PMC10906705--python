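import filecmp

import numpy as np
import pytest

from aerosolwatch import SyntheticConfig, generate_study, read_particle_csv
from aerosolwatch.errors import ValidationError
from aerosolwatch.io import read_annotations, read_procedure_record
from aerosolwatch.synthetic import (
    TruthManifest,
    generate_background,
    generate_procedure,
    inject_event,
)


class TestBackground:
    def test_degenerate_process_is_constant_intensity(self):
        cfg = SyntheticConfig(bg_innovation_sd=0.0, bg_drift_per_hour=0.0)
        rng = np.random.default_rng(0)
        counts = generate_background(cfg, 7000.0, rng)
        # intensity is constant, so per-interval totals are iid Poisson
        totals = counts.sum(axis=1)
        assert abs(totals.mean() - cfg.bg_mean_rate) < 1.0

    def test_seed_determinism(self):
        cfg = SyntheticConfig()
        a = generate_background(cfg, 3500.0, np.random.default_rng(5))
        b = generate_background(cfg, 3500.0, np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)

    def test_lag1_autocorrelation_tracks_ar_coefficient(self):
        # intensity-dominated regime so Poisson noise does not mask the
        # autoregressive structure of the log intensity
        cfg = SyntheticConfig(
            bg_mean_rate=5000.0, bg_ar_coeff=0.8, bg_innovation_sd=0.2,
            bg_drift_per_hour=0.0,
        )
        counts = generate_background(cfg, 70000.0, np.random.default_rng(11))
        x = np.log(counts.sum(axis=1))
        x = x - x.mean()
        r1 = np.dot(x[1:], x[:-1]) / np.dot(x, x)
        assert abs(r1 - 0.8) < 0.05


class TestInjectEvent:
    def test_degenerate_amplitude_single_interval(self):
        cfg = SyntheticConfig(
            amplitudes={"burp": (100.0, 0.0)},
            amplitude_sigma_log=0.0,
            decay_intervals=1,
        )
        counts = np.zeros((50, 6), dtype=np.int64)
        ts = np.arange(50) * 7.0
        truth = inject_event(counts, ts, 70.0, "burp", cfg, np.random.default_rng(0))
        assert counts.sum() == 100
        assert counts[10].sum() == 100  # the interval starting at the event time
        assert truth["aerosol_total"] == 100

    def test_zero_amplitude_leaves_series_unchanged(self):
        cfg = SyntheticConfig(amplitudes={"burp": (0.0, 0.0)})
        counts = np.zeros((50, 6), dtype=np.int64)
        inject_event(counts, np.arange(50) * 7.0, 70.0, "burp", cfg,
                     np.random.default_rng(0))
        assert counts.sum() == 0

    def test_throat_spray_favours_aerosol_fraction(self):
        # configured ordering: spray boosts aerosols (~138x null) far more
        # than droplets (~16x null)
        cfg = SyntheticConfig(amplitude_sigma_log=0.0)
        counts = np.zeros((60, 6), dtype=np.int64)
        truth = inject_event(counts, np.arange(60) * 7.0, 140.0, "throat_spray", cfg,
                             np.random.default_rng(1))
        assert truth["aerosol_total"] > 5 * truth["droplet_total"]


class TestGenerateStudy:
    def test_default_study_counts_and_parseability(self, tmp_path):
        cfg = SyntheticConfig(n_egd=3, n_cytosponge=2, seed=1)
        study = generate_study(cfg, out_dir=tmp_path)
        assert len(study.records) == 5
        for _, record in study:
            assert record.procedure_start_s >= 300.0
            stem = record.procedure_id
            frame = read_particle_csv(tmp_path / f"{stem}_particles.csv")
            assert frame.counts.min() >= 0
            back = read_procedure_record(tmp_path / f"{stem}_record.json")
            assert back.arm == record.arm
            anns = read_annotations(tmp_path / f"{stem}_annotations.csv")
            assert [a.label for a in anns] == [a.label for a in record.annotations]

    def test_byte_identical_reproducibility(self, tmp_path):
        cfg = SyntheticConfig(n_egd=3, n_cytosponge=2, seed=9)
        generate_study(cfg, out_dir=tmp_path / "a")
        generate_study(cfg, out_dir=tmp_path / "b")
        names = sorted(p.name for p in (tmp_path / "a").iterdir())
        assert names == sorted(p.name for p in (tmp_path / "b").iterdir())
        match, mismatch, errors = filecmp.cmpfiles(
            tmp_path / "a", tmp_path / "b", names, shallow=False
        )
        assert not mismatch and not errors

    def test_truth_manifest_decomposition(self):
        """Background + source + recorded injections reproduce each trace."""
        cfg = SyntheticConfig(n_egd=2, n_cytosponge=2, seed=3)
        study = generate_study(cfg)
        for frame, truth in zip(study.frames, study.manifest.procedures):
            base = np.zeros_like(frame.counts)
            for ev in truth["events"]:
                for inj in ev["injected"]:
                    base[inj["interval"]] += np.array(inj["counts"])
            residual = frame.counts - base
            assert residual.min() >= 0  # injections never exceed the trace
            assert residual.sum() + base.sum() == frame.counts.sum()

    def test_manifest_roundtrip(self):
        cfg = SyntheticConfig(n_egd=2, n_cytosponge=2, seed=4)
        manifest = generate_study(cfg).manifest
        back = TruthManifest.from_json(manifest.to_json())
        # canonical serialised form is preserved exactly
        assert back.to_json() == manifest.to_json()
        assert back.seed == manifest.seed
        assert back.procedures == [
            __import__("json").loads(__import__("json").dumps(p))
            for p in manifest.procedures
        ]

    def test_burp_rates_converge_to_configured_means(self):
        cfg = SyntheticConfig()
        ss = np.random.SeedSequence(77)
        children = ss.spawn(500)
        rates = []
        for i in range(500):
            _, record, _ = generate_procedure(cfg, "Cytosponge", i, children[i])
            n_burps = sum(1 for a in record.annotations if a.label == "burp")
            rates.append(n_burps * 20.0 / record.duration_min)
        assert np.mean(rates) == pytest.approx(cfg.burp_rate_cyto, rel=0.10)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValidationError):
            SyntheticConfig(n_egd=1)
        with pytest.raises(ValidationError):
            SyntheticConfig(bg_ar_coeff=1.2)


def test_egd_arm_scales_burp_aerosol():
    cfg = SyntheticConfig(amplitude_sigma_log=0.0, decay_intervals=1)
    c_egd = np.zeros((60, 6), dtype=np.int64)
    c_cyt = np.zeros((60, 6), dtype=np.int64)
    ts = np.arange(60) * 7.0
    t_egd = inject_event(c_egd, ts, 140.0, "burp", cfg, np.random.default_rng(0), arm="EGD")
    t_cyt = inject_event(c_cyt, ts, 140.0, "burp", cfg, np.random.default_rng(0),
                         arm="Cytosponge")
    assert t_egd["aerosol_total"] == pytest.approx(2.82 * t_cyt["aerosol_total"], rel=0.02)
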