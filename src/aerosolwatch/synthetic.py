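"""Ground-truth synthetic two-arm particle-counter studies.

Emulates the measurement setting the analysis assumes: a slowly drifting
room particle background (first-order autoregression on log intensity,
Poisson-rounded into integer channel counts), a continuous
procedure-attributable particle source whose per-unit-time rate differs
between arms by a configured fold, and short log-normally distributed
event transients (insertion/intubation, removal/extubation, throat
spray, burps) decayed geometrically over a few 7-second intervals.

Every generated study is fully reproducible from its seed, and a
:class:`TruthManifest` records the injected event counts so analyses can
be validated against known ground truth.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .io import (
    DEFAULT_CHANNEL_BANK,
    EventAnnotation,
    ParticleFrame,
    ProcedureRecord,
    SizeChannelSpec,
    write_annotations,
    write_particle_csv,
    write_procedure_record,
)

__all__ = [
    "SyntheticConfig",
    "TruthManifest",
    "SyntheticStudy",
    "generate_background",
    "inject_event",
    "generate_procedure",
    "generate_study",
    "estimate_null_excess",
    "calibrated_amplitude",
]

# Per-event amplitude medians (counts added over the whole transient), by
# label and size fraction.  Set by the calibration rule
# ``median = fold * null_excess_scale / exp(sigma_log^2 / 2)`` (see
# :func:`calibrated_amplitude`) with the fold excesses observed in
# clinical recordings (aerosol/droplet: removal 14.6x/62.6x null, throat
# spray 138x/16.2x, burps marginal/14.6x, insertion ~1x) and the default
# background + source null-excess scales (~12 aerosol, ~4.5 droplet
# counts).
DEFAULT_AMPLITUDES: dict[str, tuple[float, float]] = {
    "insertion": (9.0, 3.3),
    "removal": (127.0, 205.0),
    "intubation": (9.0, 3.3),
    "extubation": (127.0, 205.0),
    "throat_spray": (1203.0, 53.0),
    "burp": (26.0, 48.0),
}

# Fold applied to event amplitudes in the EGD arm (aerosol, droplet):
# EGD burps produce more aerosol than Cytosponge burps; EGD throat spray
# produces more droplets (patient supine rather than seated upright).
DEFAULT_EGD_EVENT_SCALE: dict[str, tuple[float, float]] = {
    "burp": (2.82, 1.0),
    "throat_spray": (1.0, 9.8),
}


@dataclass
class SyntheticConfig:
    """Study-design and noise parameters of the generator.

    Cohort sizes, procedure durations, burp rates and throat-spray usage
    default to the observed two-arm study design (37 EGD vs 18
    Cytosponge; mean durations 7.2 and 8.1 min; burp rates 1.97 and 1.46
    per 20 min; spray for all EGD and ~22% of Cytosponge patients).
    """

    n_egd: int = 37
    n_cytosponge: int = 18
    sample_period_s: float = 7.0
    channel_bank: tuple[SizeChannelSpec, ...] = DEFAULT_CHANNEL_BANK
    channel_alpha: float = 2.2  # power-law decay of counts across channels

    # room background: AR(1) on log intensity, Poisson-rounded counts
    bg_mean_rate: float = 20.0  # counts per interval, summed over channels
    bg_ar_coeff: float = 0.9
    bg_innovation_sd: float = 0.05  # log-scale
    bg_drift_per_hour: float = 0.1  # log-units per hour

    # continuous procedure-attributable source (Cytosponge-arm rates,
    # counts per interval); the arm fold multiplies the EGD arm
    proc_aerosol_rate: float = 230.0
    proc_droplet_rate: float = 25.0
    arm_fold_aerosol: float = 2.16
    arm_fold_droplet: float = 1.0
    procedure_sigma_log: float = 0.6  # between-patient production spread

    # procedure timing
    duration_mean_min_egd: float = 7.2
    duration_mean_min_cyto: float = 8.1
    duration_sigma_log: float = 0.25
    pre_roll_s: float = 420.0  # recording before procedure start
    post_roll_s: float = 63.0

    # event schedule and amplitudes
    burp_rate_egd: float = 1.97  # per 20 minutes
    burp_rate_cyto: float = 1.46
    p_spray_cyto: float = 4.0 / 18.0
    amplitudes: dict = field(default_factory=lambda: dict(DEFAULT_AMPLITUDES))
    egd_event_scale: dict = field(default_factory=lambda: dict(DEFAULT_EGD_EVENT_SCALE))
    amplitude_sigma_log: float = 0.8
    decay_intervals: int = 3
    decay_ratio: float = 0.5

    seed: int = 0

    def __post_init__(self):
        if self.n_egd < 2 or self.n_cytosponge < 2:
            raise ValidationError("cohort sizes must be >= 2")
        if not (0.0 <= self.bg_ar_coeff < 1.0):
            raise ValidationError("bg_ar_coeff must be in [0, 1)")
        for name in (
            "bg_mean_rate",
            "proc_aerosol_rate",
            "proc_droplet_rate",
            "arm_fold_aerosol",
            "arm_fold_droplet",
            "duration_mean_min_egd",
            "duration_mean_min_cyto",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.bg_innovation_sd < 0 or self.amplitude_sigma_log < 0:
            raise ValidationError("scale parameters must be non-negative")
        if self.pre_roll_s < 300.0:
            raise ValidationError("pre_roll_s must allow a 5-minute reference window")

    # -- derived helpers ---------------------------------------------------

    @property
    def channel_weights(self) -> np.ndarray:
        w = (np.arange(len(self.channel_bank)) + 1.0) ** -self.channel_alpha
        return w / w.sum()

    def fraction_columns(self, cutoff_um: float = 5.0):
        aer = [j for j, c in enumerate(self.channel_bank) if c.upper_um <= cutoff_um]
        dro = [j for j, c in enumerate(self.channel_bank) if c.lower_um >= cutoff_um]
        return aer, dro

    def decay_weights(self) -> np.ndarray:
        w = self.decay_ratio ** np.arange(self.decay_intervals)
        return w / w.sum()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["channel_bank"] = [[c.lower_um, c.upper_um] for c in self.channel_bank]
        return d


@dataclass
class TruthManifest:
    """Ground truth of a generated study: who got what, when, how much."""

    seed: int
    config: dict
    arm_fold_aerosol: float
    arm_fold_droplet: float
    procedures: list

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthManifest":
        return cls(**json.loads(text))


@dataclass
class SyntheticStudy:
    """In-memory result of :func:`generate_study`."""

    frames: list
    records: list
    manifest: TruthManifest

    def __iter__(self):
        return iter(zip(self.frames, self.records))


def _fraction_weights(config: SyntheticConfig, cols) -> np.ndarray:
    w = config.channel_weights[cols]
    return w / w.sum()


def generate_background(
    config: SyntheticConfig, duration_s: float, rng: np.random.Generator
) -> np.ndarray:
    """Slowly varying room background counts, shape ``(n_intervals, n_channels)``.

    Log intensity follows a stationary AR(1) around a linearly drifting
    mean; the intensity is split across channels by the power-law weight
    vector and Poisson-rounded to integers.
    """
    period = config.sample_period_s
    n = int(round(duration_s / period))
    if n < 10:
        raise ValidationError(f"duration {duration_s:g}s is under 10 sample intervals")
    phi, sd = config.bg_ar_coeff, config.bg_innovation_sd
    x = np.zeros(n)
    if sd > 0:
        innov = rng.normal(0.0, sd, size=n)
        stat_sd = sd / np.sqrt(1.0 - phi**2)
        x[0] = rng.normal(0.0, stat_sd)
        for t in range(1, n):
            x[t] = phi * x[t - 1] + innov[t]
    drift = config.bg_drift_per_hour * (np.arange(n) * period) / 3600.0
    rates = np.exp(np.log(config.bg_mean_rate) + drift + x)
    lam = rates[:, None] * config.channel_weights[None, :]
    return rng.poisson(lam).astype(np.int64)


def inject_event(
    counts: np.ndarray,
    timestamps: np.ndarray,
    time_s: float,
    label: str,
    config: SyntheticConfig,
    rng: np.random.Generator,
    arm: str = "Cytosponge",
) -> dict:
    """Add one event transient to ``counts`` in place; return its truth record.

    One log-normal amplitude draw (shared across fractions) scales the
    per-fraction median amplitudes; the total is decayed geometrically
    over ``decay_intervals`` intervals and split across the channels of
    each fraction by a multinomial draw, so injected counts are integers
    and sum exactly to the recorded totals.
    """
    if label not in config.amplitudes:
        raise ValidationError(f"no amplitude configured for label {label!r}")
    period = config.sample_period_s
    if not (timestamps[0] <= time_s <= timestamps[-1] + period):
        raise ValidationError(f"event time {time_s:g}s outside the recording")
    # first interval beginning at or after the event time, matching the
    # half-open event windows used downstream
    start_idx = int(np.ceil((time_s - timestamps[0]) / period))
    med_aer, med_dro = config.amplitudes[label]
    if arm == "EGD" and label in config.egd_event_scale:
        sa, sd_ = config.egd_event_scale[label]
        med_aer, med_dro = med_aer * sa, med_dro * sd_
    z = rng.normal(0.0, 1.0) if config.amplitude_sigma_log > 0 else 0.0
    scale = np.exp(config.amplitude_sigma_log * z)
    decay = config.decay_weights()
    aer_cols, dro_cols = config.fraction_columns()
    injected = []
    totals = {"aerosol": 0, "droplet": 0}
    for k, w in enumerate(decay):
        idx = start_idx + k
        if idx >= counts.shape[0]:
            break
        row = np.zeros(counts.shape[1], dtype=np.int64)
        for name, med, cols in (
            ("aerosol", med_aer, aer_cols),
            ("droplet", med_dro, dro_cols),
        ):
            total = int(np.rint(med * scale * w))
            if total > 0 and cols:
                row[cols] = rng.multinomial(total, _fraction_weights(config, cols))
                totals[name] += total
        counts[idx] += row
        injected.append({"interval": idx, "counts": row.tolist()})
    return {
        "label": label,
        "time_s": float(time_s),
        "amplitude_scale": float(scale),
        "aerosol_total": int(totals["aerosol"]),
        "droplet_total": int(totals["droplet"]),
        "injected": injected,
    }


def _sample_demographics(arm: str, rng: np.random.Generator) -> dict:
    if arm == "EGD":
        age = float(np.clip(rng.normal(61.0, 15.0), 24.0, 93.0))
        bmi = float(np.clip(rng.normal(25.5, 4.5), 16.0, 39.0))
        male = bool(rng.random() < 23.0 / 37.0)
        smoker = bool(rng.random() < 9.0 / 37.0)
    else:
        age = float(np.clip(rng.normal(64.0, 10.0), 40.0, 78.0))
        bmi = float(np.clip(rng.normal(27.0, 3.0), 22.0, 35.0))
        male = bool(rng.random() < 16.0 / 18.0)
        smoker = bool(rng.random() < 2.0 / 18.0)
    return {
        "age": round(age, 1),
        "bmi": round(bmi, 1),
        "sex": "male" if male else "female",
        "smoker": smoker,
    }


def generate_procedure(
    config: SyntheticConfig, arm: str, index: int, seed_seq: np.random.SeedSequence
):
    """Generate one complete procedure recording.

    Returns ``(frame, record, truth)`` where ``truth`` carries the
    per-event injections, the patient production multiplier and a digest
    of the pre-injection (background + source) count matrix.
    """
    rng = np.random.default_rng(seed_seq)
    period = config.sample_period_s
    mean_dur = (
        config.duration_mean_min_egd if arm == "EGD" else config.duration_mean_min_cyto
    )
    # log-normal duration with the configured arm mean
    mu = np.log(mean_dur) - config.duration_sigma_log**2 / 2.0
    duration_min = float(
        np.clip(rng.lognormal(mu, config.duration_sigma_log), 3.0, 4.0 * mean_dur)
    )
    start_s = float(np.ceil(config.pre_roll_s / period) * period)
    end_s = start_s + duration_min * 60.0
    total_s = (np.ceil((end_s + config.post_roll_s) / period)) * period
    n = int(round(total_s / period))
    timestamps = np.arange(n) * period

    counts = generate_background(config, total_s, rng)

    # continuous procedure-attributable source
    in_proc = (timestamps >= start_s) & (timestamps < end_s)
    propensity = float(rng.lognormal(0.0, config.procedure_sigma_log))
    fold_a = config.arm_fold_aerosol if arm == "EGD" else 1.0
    fold_d = config.arm_fold_droplet if arm == "EGD" else 1.0
    aer_cols, dro_cols = config.fraction_columns()
    for rate, fold, cols in (
        (config.proc_aerosol_rate, fold_a, aer_cols),
        (config.proc_droplet_rate, fold_d, dro_cols),
    ):
        lam = rate * fold * propensity * _fraction_weights(config, cols)
        counts[np.ix_(in_proc, cols)] += rng.poisson(
            lam[None, :], size=(int(in_proc.sum()), len(cols))
        )

    pre_injection_digest = hashlib.sha256(
        np.ascontiguousarray(counts).tobytes()
    ).hexdigest()

    # event schedule
    if arm == "EGD":
        sedation = (
            "midazolam_plus_spray" if rng.random() < 16.0 / 37.0 else "throat_spray_only"
        )
        schedule = [
            ("throat_spray", start_s + rng.uniform(5.0, 15.0)),
            ("intubation", start_s + rng.uniform(100.0, 140.0)),
            ("extubation", end_s - rng.uniform(30.0, 60.0)),
        ]
        burp_rate = config.burp_rate_egd
    else:
        sprayed = rng.random() < config.p_spray_cyto
        sedation = "throat_spray_only" if sprayed else "none"
        schedule = []
        if sprayed:
            schedule.append(("throat_spray", start_s + rng.uniform(5.0, 15.0)))
        schedule += [
            ("insertion", start_s + rng.uniform(100.0, 140.0)),
            ("removal", end_s - rng.uniform(30.0, 60.0)),
        ]
        burp_rate = config.burp_rate_cyto
    n_burps = int(rng.poisson(burp_rate * duration_min / 20.0))
    margin = 60.0
    if end_s - start_s > 2 * margin:
        for t in rng.uniform(start_s + margin, end_s - margin, size=n_burps):
            schedule.append(("burp", float(t)))
    schedule.sort(key=lambda e: e[1])

    events_truth = []
    annotations = []
    for label, t in schedule:
        truth = inject_event(counts, timestamps, t, label, config, rng, arm=arm)
        events_truth.append(truth)
        annotations.append(EventAnnotation(time_s=t, label=label))

    procedure_id = f"{arm[:3].upper()}{index:03d}"
    frame = ParticleFrame(
        timestamps=timestamps,
        counts=counts,
        channels=config.channel_bank,
        sample_period_s=period,
    )
    record = ProcedureRecord(
        procedure_id=procedure_id,
        arm=arm,
        procedure_start_s=start_s,
        procedure_end_s=end_s,
        sedation=sedation,
        demographics=_sample_demographics(arm, rng),
        annotations=annotations,
    )
    truth = {
        "procedure_id": procedure_id,
        "arm": arm,
        "seed_index": index,
        "duration_min": duration_min,
        "procedure_start_s": start_s,
        "procedure_end_s": end_s,
        "propensity": propensity,
        "pre_injection_digest": pre_injection_digest,
        "events": events_truth,
    }
    return frame, record, truth


def generate_study(config: SyntheticConfig, out_dir: str | Path | None = None) -> SyntheticStudy:
    """Generate a complete two-arm study, optionally writing it to disk.

    Emits, per procedure, a particle CSV, an annotation CSV and a
    metadata JSON in the package's file dialects, plus a
    ``manifest.json`` with the full ground truth.  Identical config and
    seed give byte-identical output.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_egd + config.n_cytosponge)
    frames, records, truths = [], [], []
    arms = ["EGD"] * config.n_egd + ["Cytosponge"] * config.n_cytosponge
    for i, arm in enumerate(arms):
        frame, record, truth = generate_procedure(config, arm, i, children[i])
        frames.append(frame)
        records.append(record)
        truths.append(truth)
    manifest = TruthManifest(
        seed=config.seed,
        config=config.to_dict(),
        arm_fold_aerosol=config.arm_fold_aerosol,
        arm_fold_droplet=config.arm_fold_droplet,
        procedures=truths,
    )
    study = SyntheticStudy(frames=frames, records=records, manifest=manifest)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for frame, record in study:
            stem = record.procedure_id
            write_particle_csv(frame, out / f"{stem}_particles.csv")
            write_annotations(record.annotations, out / f"{stem}_annotations.csv")
            write_procedure_record(record, out / f"{stem}_record.json")
        (out / "manifest.json").write_text(manifest.to_json() + "\n")
    return study


# ---------------------------------------------------------------------------
# calibration helpers


def estimate_null_excess(
    config: SyntheticConfig,
    fraction: str = "aerosol",
    arm: str = "Cytosponge",
    n_procedures: int = 12,
    nulls_per_procedure: int = 3,
    event_window_s: float = 21.0,
    baseline_window_s: float = 70.0,
    seed: int = 12345,
) -> float:
    """Expected mean positive null-window excess under a given configuration.

    Monte-Carlo estimate that mirrors the pipeline's null sampling
    exactly: procedures are generated with their configured event
    schedule, and null windows are drawn at least ``min_gap`` from every
    annotation and one baseline window clear of the procedure onset.
    This is the denominator scale of event-vs-null fold changes.
    """
    from .event_analysis import SamplingError, sample_null_events
    from .preprocess import aggregate_size_fractions

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_procedures)
    vals = []
    for i in range(n_procedures):
        frame, record, _ = generate_procedure(config, arm, i, children[i])
        series = aggregate_size_fractions(frame)
        try:
            nulls = sample_null_events(
                series,
                record.annotations,
                nulls_per_procedure,
                min_gap_s=60.0,
                rng_seed=np.random.default_rng(children[i].spawn(1)[0]),
                event_window_s=event_window_s,
                baseline_window_s=baseline_window_s,
                within=(
                    record.procedure_start_s + baseline_window_s,
                    record.procedure_end_s,
                ),
                allow_fewer=True,
            )
        except SamplingError:
            continue
        vals.extend(max(e.value(fraction), 0.0) for e in nulls)
    return float(np.mean(vals))


def calibrated_amplitude(
    config: SyntheticConfig,
    target_fold: float,
    fraction: str = "aerosol",
    arm: str = "Cytosponge",
    **kwargs,
) -> float:
    """Amplitude median giving an expected event excess of ``target_fold`` x null.

    The expected event excess equals the log-normal amplitude mean
    ``median * exp(sigma^2 / 2)``, so the median is the target fold times
    the null-excess scale divided by that factor.
    """
    eps = estimate_null_excess(config, fraction=fraction, arm=arm, **kwargs)
    return target_fold * eps / float(np.exp(config.amplitude_sigma_log**2 / 2.0))
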