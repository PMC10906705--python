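"""End-to-end orchestration: ingest a study directory, run the
whole-procedure and event-based analyses, emit a results bundle.

The bundle contains (1) arm-vs-arm fold changes in 20-minute-equivalent
counts, raw and spike-filtered, for both size fractions, with and
without the throat-spray exclusion; (2) paired procedure-vs-reference
fold changes; (3) per-event-class fold excesses over sampled
null-reference windows; (4) cross-arm comparisons of matched event
classes; (5) the cohort table.  A run manifest records every parameter,
the seed and input digests, so a rerun reproduces every number exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .cohort_stats import cohort_table
from .errors import AerosolWatchError, ConfigurationError, InferenceError, SamplingError
from .event_analysis import (
    bootstrap_ratio,
    event_vs_null,
    extract_event_excess,
    sample_null_events,
)
from .io import (
    DEFAULT_CHANNEL_BANK,
    read_annotations,
    read_particle_csv,
    read_procedure_record,
    write_results,
)
from .preprocess import aggregate_size_fractions
from .whole_procedure import (
    FRACTIONS,
    VARIANTS,
    compare_arms,
    procedure_vs_reference,
    summarize_procedure,
)

logger = logging.getLogger("aerosolwatch")

__all__ = ["StudyConfig", "StudyResults", "load_study", "run_study", "run_study_frames"]

#: Cytosponge event labels and their EGD counterparts for cross-arm tests.
EVENT_PAIRS = {
    "insertion": "intubation",
    "removal": "extubation",
    "throat_spray": "throat_spray",
    "burp": "burp",
}


@dataclass
class StudyConfig:
    """Configuration of one pipeline run."""

    input_dir: str | Path
    output_dir: str | Path | None = None
    seed: int = 0
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    log_level: str = "INFO"


@dataclass
class StudyResults:
    """Results bundle of :func:`run_study`."""

    comparisons: list
    cohort: pd.DataFrame
    manifest: dict

    def to_frame(self) -> pd.DataFrame:
        import dataclasses

        return pd.DataFrame([dataclasses.asdict(r) for r in self.comparisons])

    def get(self, comparison: str, fraction: str, variant: str = ""):
        for r in self.comparisons:
            if (
                r.comparison == comparison
                and r.fraction == fraction
                and r.variant == variant
            ):
                return r
        raise KeyError((comparison, fraction, variant))


def load_study(input_dir: str | Path, channel_bank=DEFAULT_CHANNEL_BANK):
    """Load every procedure (``*_record.json`` + particle CSV) in a directory."""
    input_dir = Path(input_dir)
    if not input_dir.is_dir():
        raise ConfigurationError(f"input directory {input_dir} does not exist")
    frames, records = [], []
    record_paths = sorted(input_dir.glob("*_record.json"))
    if not record_paths:
        raise ConfigurationError(f"no *_record.json files in {input_dir}")
    for rp in record_paths:
        record = read_procedure_record(rp)
        stem = rp.name.removesuffix("_record.json")
        frame = read_particle_csv(input_dir / f"{stem}_particles.csv", channel_bank)
        ann_path = input_dir / f"{stem}_annotations.csv"
        if ann_path.exists() and not record.annotations:
            record.annotations = read_annotations(ann_path)
        frames.append(frame)
        records.append(record)
    return frames, records


def _input_digests(input_dir: Path) -> dict:
    out = {}
    for p in sorted(Path(input_dir).glob("*")):
        if p.is_file() and p.suffix in (".csv", ".json"):
            out[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    return out


def run_study_frames(
    frames,
    records,
    analysis: AnalysisConfig | None = None,
    seed: int = 0,
) -> StudyResults:
    """Run the full analysis on in-memory procedures.

    Stochastic stages (null-window sampling, bootstrap) draw from
    deterministic streams derived from ``seed``, so identical inputs and
    seed reproduce every number.
    """
    analysis = analysis or AnalysisConfig()
    if len(frames) != len(records):
        raise ConfigurationError("frames and records differ in length")
    for arm in ("EGD", "Cytosponge"):
        if sum(1 for r in records if r.arm == arm) < 2:
            raise InferenceError(f"arm {arm!r} has fewer than 2 procedures")

    comparisons = []

    # -- whole-procedure analysis -----------------------------------------
    logger.info("summarising %d procedures", len(records))
    series_by_id = {}
    summaries = []
    for frame, record in zip(frames, records):
        series = aggregate_size_fractions(frame, analysis.cutoff_um)
        series_by_id[record.procedure_id] = series
        summaries.append(summarize_procedure(series, record, analysis))

    for fraction in FRACTIONS:
        for variant in VARIANTS:
            comparisons.append(
                compare_arms(
                    summaries,
                    fraction,
                    variant,
                    pseudocount=analysis.pseudocount,
                )
            )
            try:
                comparisons.append(
                    compare_arms(
                        summaries,
                        fraction,
                        variant,
                        exclude_throat_spray_from="Cytosponge",
                        pseudocount=analysis.pseudocount,
                    )
                )
            except InferenceError as exc:
                logger.warning("skipping throat-spray exclusion (%s/%s): %s",
                               fraction, variant, exc)
            comparisons.append(
                procedure_vs_reference(
                    summaries,
                    fraction,
                    variant,
                    arm="Cytosponge",
                    pseudocount=analysis.pseudocount,
                )
            )

    # -- event-based analysis ----------------------------------------------
    logger.info("extracting event excesses")
    events_by = {"EGD": {}, "Cytosponge": {}}
    nulls_by = {"EGD": [], "Cytosponge": []}
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(1,))
    children = ss.spawn(len(records))
    for child, record in zip(children, records):
        series = series_by_id[record.procedure_id]
        for ann in record.annotations:
            try:
                ev = extract_event_excess(
                    series,
                    ann,
                    event_window_s=analysis.event_window_s,
                    baseline_window_s=analysis.baseline_window_s,
                )
            except AerosolWatchError as exc:
                logger.warning("%s: skipping %s@%gs: %s",
                               record.procedure_id, ann.label, ann.time_s, exc)
                continue
            ev.procedure_id = record.procedure_id
            events_by[record.arm].setdefault(ann.label, []).append(ev)
        try:
            nulls = sample_null_events(
                series,
                record.annotations,
                analysis.n_null_events,
                min_gap_s=analysis.min_gap_s,
                rng_seed=np.random.default_rng(child),
                event_window_s=analysis.event_window_s,
                baseline_window_s=analysis.baseline_window_s,
                # stay one baseline window clear of the procedure onset so
                # the local baseline is not contaminated by the step in
                # procedure-attributable production
                within=(
                    record.procedure_start_s + analysis.baseline_window_s,
                    record.procedure_end_s,
                ),
                allow_fewer=True,
            )
            for ev in nulls:
                ev.procedure_id = record.procedure_id
            nulls_by[record.arm].extend(nulls)
        except SamplingError as exc:
            logger.warning("%s: no null windows: %s", record.procedure_id, exc)

    boot_ss = np.random.SeedSequence(entropy=seed, spawn_key=(2,))
    boot_rng = np.random.default_rng(boot_ss)
    for label in ("insertion", "removal", "throat_spray", "burp"):
        events = events_by["Cytosponge"].get(label, [])
        for fraction in FRACTIONS:
            if len(events) >= 2 and nulls_by["Cytosponge"]:
                comparisons.append(
                    event_vs_null(
                        events,
                        nulls_by["Cytosponge"],
                        fraction=fraction,
                        n_boot=analysis.n_boot,
                        rng_seed=boot_rng,
                        statistic=analysis.ratio_statistic,
                        floor=analysis.ratio_floor,
                    )
                )
            egd_label = EVENT_PAIRS[label]
            egd_events = events_by["EGD"].get(egd_label, [])
            if len(events) >= 2 and len(egd_events) >= 2:
                est = bootstrap_ratio(
                    events,
                    egd_events,
                    fraction=fraction,
                    n_boot=analysis.n_boot,
                    rng_seed=boot_rng,
                    statistic=analysis.ratio_statistic,
                    floor=analysis.ratio_floor,
                    comparison=f"{label}_Cytosponge_vs_{egd_label}_EGD",
                )
                comparisons.append(est)

    cohort = cohort_table(records)

    manifest = {
        "seed": seed,
        "analysis": analysis.to_dict(),
        "n_procedures": len(records),
        "n_comparisons": len(comparisons),
    }
    return StudyResults(comparisons=comparisons, cohort=cohort, manifest=manifest)


def run_study(config: StudyConfig) -> StudyResults:
    """Load a study directory, run every analysis, write the results bundle.

    Outputs (when ``output_dir`` is set): ``results.csv`` (all fold
    changes), ``cohort.csv``, ``report.txt`` and ``run_manifest.json``.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    input_dir = Path(config.input_dir)
    if not input_dir.is_dir():
        raise ConfigurationError(f"input directory {input_dir} does not exist")
    frames, records = load_study(input_dir)
    results = run_study_frames(frames, records, config.analysis, config.seed)
    results.manifest["input_dir"] = str(input_dir)
    results.manifest["input_digests"] = _input_digests(input_dir)
    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_results(results.comparisons, out / "results.csv")
        results.cohort.to_csv(out / "cohort.csv", index=False, float_format="%.12g")
        (out / "run_manifest.json").write_text(
            json.dumps(results.manifest, indent=2, sort_keys=True) + "\n"
        )
        (out / "report.txt").write_text(format_report(results))
    return results


def format_report(results: StudyResults) -> str:
    """Human-readable summary of a results bundle."""
    lines = ["aerosolwatch study report", "=" * 60, ""]
    lines.append("Whole-procedure and event fold changes (95% CI, two-sided p):")
    for r in results.comparisons:
        star = (
            "***" if r.p_value < 0.001 else "**" if r.p_value < 0.01
            else "*" if r.p_value < 0.05 else ""
        )
        tag = f"{r.comparison} [{r.fraction}{'/' + r.variant if r.variant else ''}]"
        lines.append(
            f"  {tag:58s} {r.ratio:8.2f}x  ({r.ci_low:.2f}-{r.ci_high:.2f})  "
            f"p={r.p_value:.4g} {star}  n={r.n_a}/{r.n_b}"
        )
    lines += ["", "Cohort comparison:"]
    lines.append(results.cohort.to_string(index=False))
    lines.append("")
    return "\n".join(lines)
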