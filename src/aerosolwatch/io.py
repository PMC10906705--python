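"""Core data model and file I/O.

The package analyses six-channel optical particle-counter recordings of
clinical procedures.  The counter reports differential particle counts in
six diameter ranges (0.5-0.7, 0.7-1.0, 1.0-3.0, 3.0-5.0, 5.0-10.0 and
10.0-25.0 um) at a flow rate of 100 L/min, averaged over 7-second
intervals.  A recording is represented by :class:`ParticleFrame`;
procedure events (insertion, removal, throat spray, burps, ...) by
:class:`EventAnnotation`; and one patient procedure by
:class:`ProcedureRecord`.

File dialects
-------------
particle CSV
    ``time_s,c0.5_0.7,c0.7_1.0,c1.0_3.0,c3.0_5.0,c5.0_10.0,c10.0_25.0``;
    one row per averaging interval, timestamps are interval starts in
    seconds since recording start (half-open intervals ``[t, t+period)``).
annotations CSV
    ``time_s,label`` with labels from :data:`EVENT_LABELS`.
procedure metadata
    JSON with the :class:`ProcedureRecord` fields.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError, VocabularyError

__all__ = [
    "SizeChannelSpec",
    "DEFAULT_CHANNEL_BANK",
    "EVENT_LABELS",
    "ARMS",
    "SEDATION_LEVELS",
    "ParticleFrame",
    "EventAnnotation",
    "ProcedureRecord",
    "AggregateSeries",
    "read_particle_csv",
    "write_particle_csv",
    "read_annotations",
    "write_annotations",
    "read_procedure_record",
    "write_procedure_record",
    "write_results",
    "read_results",
]

#: Closed vocabulary of procedure event labels.  ``burp`` covers any
#: involuntary audible expulsion of air from the mouth, including coughing
#: and gagging; there is deliberately no separate ``cough`` label.
EVENT_LABELS = frozenset(
    {
        "insertion",
        "removal",
        "intubation",
        "extubation",
        "throat_spray",
        "burp",
        "null_reference",
    }
)

ARMS = ("EGD", "Cytosponge")
SEDATION_LEVELS = ("none", "throat_spray_only", "midazolam_plus_spray")


@dataclass(frozen=True)
class SizeChannelSpec:
    """One particle-size channel, a half-open diameter range in micrometres."""

    lower_um: float
    upper_um: float

    def __post_init__(self):
        if not self.lower_um < self.upper_um:
            raise ValidationError(
                f"channel bounds must satisfy lower < upper, got "
                f"[{self.lower_um}, {self.upper_um}]"
            )

    @property
    def column_name(self) -> str:
        def fmt(x: float) -> str:
            return f"{x:.1f}" if abs(x * 10 - round(x * 10)) < 1e-9 else f"{x:g}"

        return f"c{fmt(self.lower_um)}_{fmt(self.upper_um)}"


#: The counter's six diameter ranges, contiguous and non-overlapping.
DEFAULT_CHANNEL_BANK: tuple[SizeChannelSpec, ...] = (
    SizeChannelSpec(0.5, 0.7),
    SizeChannelSpec(0.7, 1.0),
    SizeChannelSpec(1.0, 3.0),
    SizeChannelSpec(3.0, 5.0),
    SizeChannelSpec(5.0, 10.0),
    SizeChannelSpec(10.0, 25.0),
)


def _validate_channel_bank(bank: Sequence[SizeChannelSpec]) -> tuple[SizeChannelSpec, ...]:
    bank = tuple(bank)
    if not bank:
        raise ValidationError("channel bank is empty")
    for lo, hi in zip(bank, bank[1:]):
        if hi.lower_um < lo.upper_um:
            raise ValidationError(
                f"channels overlap: [{lo.lower_um},{lo.upper_um}] and "
                f"[{hi.lower_um},{hi.upper_um}]"
            )
    return bank


@dataclass
class ParticleFrame:
    """Timestamped multi-channel particle counts for one recording session.

    Parameters
    ----------
    timestamps
        Interval-start times in seconds since recording start, strictly
        increasing and spaced by ``sample_period_s`` (1% tolerance).
    counts
        Non-negative integer matrix, shape ``(n_samples, n_channels)``;
        differential counts per channel per averaging interval.
    channels
        One :class:`SizeChannelSpec` per column of ``counts``.
    sample_period_s
        Averaging interval of the instrument; 7 s by default.
    flow_rate_lpm
        Sample flow rate in litres per minute; 100 by default.
    """

    timestamps: np.ndarray
    counts: np.ndarray
    channels: tuple[SizeChannelSpec, ...] = DEFAULT_CHANNEL_BANK
    sample_period_s: float = 7.0
    flow_rate_lpm: float = 100.0

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        counts = np.asarray(self.counts)
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            if not np.allclose(counts, rounded, atol=1e-9):
                raise ValidationError("counts must be integers")
            counts = rounded.astype(np.int64)
        self.counts = counts.astype(np.int64, copy=False)
        self.channels = _validate_channel_bank(self.channels)
        if self.counts.ndim != 2 or self.counts.shape[1] != len(self.channels):
            raise ValidationError(
                f"counts must have one column per channel: shape "
                f"{self.counts.shape} vs {len(self.channels)} channels"
            )
        if self.timestamps.shape[0] != self.counts.shape[0]:
            raise ValidationError("timestamps and counts lengths differ")
        if np.any(self.counts < 0):
            bad = int(np.argwhere(self.counts < 0)[0, 0])
            raise ValidationError(f"negative count at row {bad}")
        if len(self.timestamps) > 1:
            gaps = np.diff(self.timestamps)
            if np.any(gaps <= 0):
                raise ValidationError("timestamps must be strictly increasing")
            tol = 0.01 * self.sample_period_s
            if np.any(np.abs(gaps - self.sample_period_s) > tol):
                bad = int(np.argmax(np.abs(gaps - self.sample_period_s) > tol))
                raise ValidationError(
                    f"timestamp gap {gaps[bad]:g}s at row {bad + 1} deviates from "
                    f"sample period {self.sample_period_s:g}s by more than 1%"
                )

    @property
    def n_samples(self) -> int:
        return int(self.counts.shape[0])

    @property
    def duration_s(self) -> float:
        """Total recorded span, counting the last interval in full."""
        if self.n_samples == 0:
            return 0.0
        return float(self.timestamps[-1] - self.timestamps[0] + self.sample_period_s)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=[c.column_name for c in self.channels])
        df.insert(0, "time_s", self.timestamps)
        return df


@dataclass(frozen=True, order=True)
class EventAnnotation:
    """A labelled, timestamped procedure event."""

    time_s: float
    label: str

    def __post_init__(self):
        if self.label not in EVENT_LABELS:
            raise VocabularyError(
                f"unknown event label {self.label!r}; accepted labels: "
                f"{', '.join(sorted(EVENT_LABELS))}"
            )


@dataclass
class ProcedureRecord:
    """One patient procedure: arm, timing, sedation, demographics, events.

    ``procedure_start_s``/``procedure_end_s`` are seconds since recording
    start.  A reference window of at least 5 minutes must exist before the
    procedure start; :attr:`has_reference_headroom` flags whether it does.
    """

    procedure_id: str
    arm: str
    procedure_start_s: float
    procedure_end_s: float
    sedation: str = "none"
    demographics: dict = field(default_factory=dict)
    annotations: list[EventAnnotation] = field(default_factory=list)

    def __post_init__(self):
        if self.arm not in ARMS:
            raise ValidationError(f"arm must be one of {ARMS}, got {self.arm!r}")
        if self.sedation not in SEDATION_LEVELS:
            raise ValidationError(
                f"sedation must be one of {SEDATION_LEVELS}, got {self.sedation!r}"
            )
        if not self.procedure_start_s < self.procedure_end_s:
            raise ValidationError("procedure_start_s must precede procedure_end_s")
        self.annotations = sorted(self.annotations)

    @property
    def duration_min(self) -> float:
        return (self.procedure_end_s - self.procedure_start_s) / 60.0

    @property
    def has_reference_headroom(self) -> bool:
        """True if >= 5 minutes of recording precede the procedure."""
        return self.procedure_start_s >= 300.0

    @property
    def used_throat_spray(self) -> bool:
        return self.sedation in ("throat_spray_only", "midazolam_plus_spray")


@dataclass
class AggregateSeries:
    """Per-interval totals in the aerosol (<=5 um) and droplet (>5 um) fractions."""

    timestamps: np.ndarray
    aerosol_counts: np.ndarray
    droplet_counts: np.ndarray
    sample_period_s: float = 7.0

    def fraction(self, name: str) -> np.ndarray:
        if name == "aerosol":
            return self.aerosol_counts
        if name == "droplet":
            return self.droplet_counts
        raise ValidationError(f"unknown size fraction {name!r}")


# ---------------------------------------------------------------------------
# readers / writers


def read_particle_csv(
    path: str | Path,
    channel_bank: Sequence[SizeChannelSpec] = DEFAULT_CHANNEL_BANK,
    sample_period_s: float = 7.0,
    flow_rate_lpm: float = 100.0,
    cumulative: bool = False,
) -> ParticleFrame:
    """Read a particle-counter CSV into a :class:`ParticleFrame`.

    The header must contain ``time_s`` plus one ``c<lower>_<upper>``
    column per channel in the bank.  With ``cumulative=True`` the columns
    are interpreted as cumulative >=size counts and differenced into
    per-channel counts.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"{path}: cannot parse CSV: {exc}") from exc
    bank = _validate_channel_bank(channel_bank)
    wanted = ["time_s"] + [c.column_name for c in bank]
    missing = [c for c in wanted if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}; found {list(df.columns)}")
    raw = df[[c.column_name for c in bank]].to_numpy()
    if np.any(~np.isfinite(raw)):
        row = int(np.argwhere(~np.isfinite(raw))[0, 0])
        raise ValidationError(f"{path}: non-finite count at data row {row + 1}")
    if cumulative:
        raw = raw - np.concatenate([raw[:, 1:], np.zeros((raw.shape[0], 1))], axis=1)
    if np.any(raw < 0):
        row = int(np.argwhere(raw < 0)[0, 0])
        raise ValidationError(f"{path}: negative count at data row {row + 1}")
    try:
        return ParticleFrame(
            timestamps=df["time_s"].to_numpy(dtype=float),
            counts=raw,
            channels=bank,
            sample_period_s=sample_period_s,
            flow_rate_lpm=flow_rate_lpm,
        )
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_particle_csv(frame: ParticleFrame, path: str | Path) -> Path:
    path = Path(path)
    frame.to_dataframe().to_csv(path, index=False, float_format="%.6f")
    return path


def read_annotations(path: str | Path) -> list[EventAnnotation]:
    """Read an annotation log (``time_s,label``), validated and time-sorted."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []
    for col in ("time_s", "label"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    events = [
        EventAnnotation(time_s=float(t), label=str(lab).strip())
        for t, lab in zip(df["time_s"], df["label"])
    ]
    return sorted(events)


def write_annotations(annotations: Sequence[EventAnnotation], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_s": [a.time_s for a in sorted(annotations)],
            "label": [a.label for a in sorted(annotations)],
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")
    return path


def write_procedure_record(record: ProcedureRecord, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "procedure_id": record.procedure_id,
        "arm": record.arm,
        "procedure_start_s": record.procedure_start_s,
        "procedure_end_s": record.procedure_end_s,
        "sedation": record.sedation,
        "demographics": record.demographics,
        "annotations": [
            {"time_s": a.time_s, "label": a.label} for a in record.annotations
        ],
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def read_procedure_record(path: str | Path) -> ProcedureRecord:
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON: {exc}") from exc
    try:
        annotations = [
            EventAnnotation(time_s=float(a["time_s"]), label=a["label"])
            for a in payload.get("annotations", [])
        ]
        return ProcedureRecord(
            procedure_id=payload["procedure_id"],
            arm=payload["arm"],
            procedure_start_s=float(payload["procedure_start_s"]),
            procedure_end_s=float(payload["procedure_end_s"]),
            sedation=payload.get("sedation", "none"),
            demographics=payload.get("demographics", {}),
            annotations=annotations,
        )
    except KeyError as exc:
        raise FormatError(f"{path}: missing field {exc}") from exc


#: Column order of the results table; fixed so outputs are reproducible.
RESULT_COLUMNS = (
    "comparison",
    "fraction",
    "variant",
    "ratio",
    "ci_low",
    "ci_high",
    "p_value",
    "n_a",
    "n_b",
    "method",
)


def write_results(results, path: str | Path) -> Path:
    """Write ratio estimates to CSV with a deterministic column order.

    Numeric fields are written with 12 significant digits so a read/write
    round trip preserves them to that precision.
    """
    path = Path(path)
    rows = []
    for r in results:
        d = dataclasses.asdict(r)
        rows.append({c: d.get(c, "") for c in RESULT_COLUMNS})
    df = pd.DataFrame(rows, columns=list(RESULT_COLUMNS))
    df.to_csv(path, index=False, float_format="%.12g")
    return path


def read_results(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing result columns {missing}")
    return df
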