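"""Domain types and delimited-text I/O for dyadic eye-tracking recordings.

A recording consists of a uniformly sampled pupil-diameter trace (nominally
200 Hz, left eye), interval events (blinks, fixations, saccades) reported by
the eye tracker, and a trial schedule that partitions each trial into three
consecutive 30-s phases (baseline, audio, silence). Two such recordings on a
common clock form a dyad.

All on-disk formats are plain delimited text: CSV (``.csv``) or TSV
(``.tsv``/``.txt``/``.tab``), selected by file extension. Readers validate
structure and monotonicity; they never silently repair data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("dyadsync")

#: Phase labels in their within-trial order.
PHASE_LABELS = ("baseline", "audio", "silence")
#: Emotional-context labels (one trial each, counterbalanced order).
CONTEXT_LABELS = ("neutral", "negative", "positive")
#: Participant roles within a dyad.
ROLE_LABELS = ("listener", "observer")
#: Event kinds handled by this package.
EVENT_KINDS = ("blink", "fixation", "saccade")

#: Canonical column names for a pupil-sample table.
DEFAULT_PUPIL_DIALECT: dict[str, str] = {"timestamp": "timestamp", "diameter": "diameter"}
#: Pupil Labs Neon-style export columns (timestamps in nanoseconds).
PUPIL_LABS_NEON_DIALECT: dict[str, str] = {
    "timestamp": "timestamp [ns]",
    "diameter": "pupil diameter left [mm]",
    "time_unit": "ns",
}
#: Canonical column names for an event table.
DEFAULT_EVENT_DIALECT: dict[str, str] = {"onset": "onset", "offset": "offset"}

#: Fixed column order of the long-format metrics table.
METRICS_COLUMNS = ("dyad", "participant", "role", "trial", "context", "phase", "measure", "value")

_TIME_UNIT_SCALE = {"s": 1.0, "ms": 1e-3, "us": 1e-6, "ns": 1e-9}


class FormatError(ValueError):
    """A delimited file is structurally unusable (e.g. a required column is absent)."""


class ValidationError(ValueError):
    """Parsed data violate a domain invariant (ordering, overlap, sign)."""


class RangeError(ValueError):
    """A requested window or span lies outside the data it is applied to."""


class IntegrityError(ValueError):
    """A table violates a uniqueness/completeness constraint."""


def _sep_for(path: str | Path) -> str:
    suffix = Path(path).suffix.lower()
    return "," if suffix == ".csv" else "\t"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

# Bit flags recording why a sample is in its current state. ``MISSING`` means
# absent in the source or invalidated by a preprocessing stage; the remaining
# bits record which stage acted on the sample (used for reporting and for
# idempotent gap-edge trimming).
FLAG_MISSING = 1
FLAG_INTERPOLATED = 2
FLAG_SPEED_OUTLIER = 4
FLAG_EDGE_TRIM = 8
FLAG_SPARSITY = 16


@dataclass
class PupilTrace:
    """Uniformly sampled pupil-diameter time series with a validity mask.

    ``diameter`` holds NaN wherever ``valid`` is False (the missing sentinel).
    ``interpolated`` marks samples whose value was reconstructed by linear
    interpolation during preprocessing; such samples are usable but are kept
    distinct from originally valid data. ``flags`` is a per-sample bitmask of
    provenance codes (``FLAG_*``).
    """

    timestamps: np.ndarray
    diameter: np.ndarray
    valid: np.ndarray
    interpolated: np.ndarray = field(default=None)  # type: ignore[assignment]
    flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.diameter = np.asarray(self.diameter, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.timestamps)
        if len(self.diameter) != n or len(self.valid) != n:
            raise ValidationError(
                f"length mismatch: {n} timestamps, {len(self.diameter)} diameters, "
                f"{len(self.valid)} validity flags"
            )
        if n > 1:
            dt = np.diff(self.timestamps)
            bad = np.nonzero(dt <= 0)[0]
            if bad.size:
                raise ValidationError(
                    f"timestamps not strictly increasing at index {int(bad[0]) + 1}"
                )
        if self.interpolated is None:
            self.interpolated = np.zeros(n, dtype=bool)
        else:
            self.interpolated = np.asarray(self.interpolated, dtype=bool)
        if self.flags is None:
            self.flags = np.where(self.valid, 0, FLAG_MISSING).astype(np.uint8)
        else:
            self.flags = np.asarray(self.flags, dtype=np.uint8)
        # enforce the missing sentinel
        self.diameter = np.where(self.valid, self.diameter, np.nan)

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def usable(self) -> np.ndarray:
        """Samples carrying a value: originally valid or interpolated."""
        return self.valid

    @property
    def sampling_rate(self) -> float:
        """Nominal sampling rate estimated from the median sample spacing."""
        if len(self) < 2:
            raise ValidationError("cannot estimate sampling rate from fewer than 2 samples")
        return 1.0 / float(np.median(np.diff(self.timestamps)))

    def copy(self) -> "PupilTrace":
        return PupilTrace(
            self.timestamps.copy(),
            self.diameter.copy(),
            self.valid.copy(),
            self.interpolated.copy(),
            self.flags.copy(),
        )

    def span(self) -> tuple[float, float]:
        return float(self.timestamps[0]), float(self.timestamps[-1])


@dataclass(frozen=True)
class OcularEvent:
    """A blink, fixation, or saccade interval in seconds on the recording clock."""

    kind: str
    onset: float
    offset: float

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValidationError(f"unknown event kind {self.kind!r}")
        if not self.offset > self.onset:
            raise ValidationError(
                f"event offset {self.offset} must exceed onset {self.onset}"
            )

    @property
    def duration_ms(self) -> float:
        """Event duration in milliseconds."""
        return (self.offset - self.onset) * 1000.0


@dataclass(frozen=True)
class PhaseWindow:
    """A labeled half-open interval [start, end) within one trial."""

    label: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.label not in PHASE_LABELS:
            raise ValidationError(f"unknown phase label {self.label!r}")
        if not self.end > self.start:
            raise ValidationError("phase end must exceed start")

    @property
    def length(self) -> float:
        return self.end - self.start

    def contains(self, t: float) -> bool:
        return self.start <= t < self.end


@dataclass(frozen=True)
class TrialContext:
    """Trial index (1-based), emotional context, and counterbalancing label."""

    trial_index: int
    context: str
    order_code: str = ""

    def __post_init__(self) -> None:
        if self.context not in CONTEXT_LABELS:
            raise ValidationError(f"unknown context {self.context!r}")
        if self.trial_index < 1:
            raise ValidationError("trial_index is 1-based")


ScheduleEntry = tuple[TrialContext, tuple[PhaseWindow, PhaseWindow, PhaseWindow]]


@dataclass
class ParticipantRecording:
    """One participant's trace, events, and schedule."""

    participant_id: str
    role: str
    trace: PupilTrace
    events: list[OcularEvent]
    schedule: list[ScheduleEntry]
    eye: str = "left"

    def __post_init__(self) -> None:
        if self.role not in ROLE_LABELS:
            raise ValidationError(f"unknown role {self.role!r}")
        if len(self.trace):
            t0, t1 = self.trace.span()
            for ev in self.events:
                if not (t0 <= ev.onset <= t1):
                    raise ValidationError(
                        f"{ev.kind} onset {ev.onset} outside recording span [{t0}, {t1}]"
                    )
        validate_schedule(self.schedule)

    def events_of(self, kind: str) -> list[OcularEvent]:
        return [ev for ev in self.events if ev.kind == kind]


@dataclass
class DyadRecording:
    """Two simultaneously recorded participants sharing one schedule."""

    dyad_id: str
    listener: ParticipantRecording
    observer: ParticipantRecording

    def __post_init__(self) -> None:
        if self.listener.role != "listener" or self.observer.role != "observer":
            raise ValidationError("dyad members must carry the listener/observer roles")
        for (ctx_a, wins_a), (ctx_b, wins_b) in zip(
            self.listener.schedule, self.observer.schedule, strict=True
        ):
            if ctx_a != ctx_b or wins_a != wins_b:
                raise ValidationError(
                    f"dyad {self.dyad_id}: members disagree on the trial schedule"
                )

    @property
    def schedule(self) -> list[ScheduleEntry]:
        return self.listener.schedule

    def members(self) -> tuple[ParticipantRecording, ParticipantRecording]:
        return self.listener, self.observer


def validate_schedule(schedule: Sequence[ScheduleEntry]) -> None:
    """Check phase ordering/contiguity and context uniqueness of a schedule."""
    seen: set[str] = set()
    for ctx, windows in schedule:
        if ctx.context in seen:
            raise ValidationError(f"context {ctx.context!r} appears more than once")
        seen.add(ctx.context)
        if tuple(w.label for w in windows) != PHASE_LABELS:
            raise ValidationError(
                f"trial {ctx.trial_index}: phases must be ordered {PHASE_LABELS}"
            )
        for earlier, later in zip(windows, windows[1:]):
            if not np.isclose(earlier.end, later.start, atol=1e-9):
                raise ValidationError(
                    f"trial {ctx.trial_index}: phases {earlier.label}/{later.label} "
                    "are not contiguous"
                )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_pupil_trace(path: str | Path, dialect: Mapping[str, str] | None = None) -> PupilTrace:
    """Read a pupil-sample table into a validated :class:`PupilTrace`.

    Parameters
    ----------
    path:
        CSV/TSV file with one row per sample.
    dialect:
        Map from the canonical keys ``timestamp``/``diameter`` to the file's
        column names, optionally with ``time_unit`` in {"s","ms","us","ns"}.
        Defaults to canonical names in seconds. Missing diameter samples may
        be empty cells or NaN; they become invalid samples, never values.
    """
    dialect = dict(DEFAULT_PUPIL_DIALECT) | dict(dialect or {})
    unit = dialect.pop("time_unit", "s")
    if unit not in _TIME_UNIT_SCALE:
        raise FormatError(f"unknown time unit {unit!r}")
    df = pd.read_csv(path, sep=_sep_for(path))
    for key in ("timestamp", "diameter"):
        if dialect[key] not in df.columns:
            raise FormatError(
                f"{path}: required column {dialect[key]!r} (for {key}) not found; "
                f"columns present: {list(df.columns)}"
            )
    ts = df[dialect["timestamp"]].to_numpy(dtype=float) * _TIME_UNIT_SCALE[unit]
    diam = pd.to_numeric(df[dialect["diameter"]], errors="coerce").to_numpy(dtype=float)
    valid = np.isfinite(diam)
    if len(ts) > 1:
        bad = np.nonzero(np.diff(ts) <= 0)[0]
        if bad.size:
            raise ValidationError(
                f"{path}: timestamps not strictly increasing at row {int(bad[0]) + 1}"
            )
    return PupilTrace(ts, diam, valid)


def write_pupil_trace(trace: PupilTrace, path: str | Path) -> None:
    """Write a trace as a two-column sample table (lossless round-trip partner
    of :func:`read_pupil_trace`; timestamps to microsecond precision)."""
    df = pd.DataFrame(
        {"timestamp": trace.timestamps, "diameter": trace.diameter}
    )
    df.to_csv(path, sep=_sep_for(path), index=False, float_format="%.6f", na_rep="")


def read_events(
    path: str | Path, kind: str, dialect: Mapping[str, str] | None = None
) -> list[OcularEvent]:
    """Read an onset/offset event table of one kind, validated and sorted.

    Offsets must exceed onsets and same-kind events must not overlap; either
    violation raises :class:`ValidationError` naming the offending row.
    An empty table yields an empty list with a logged warning.
    """
    if kind not in EVENT_KINDS:
        raise ValidationError(f"unknown event kind {kind!r}")
    dialect = dict(DEFAULT_EVENT_DIALECT) | dict(dialect or {})
    df = pd.read_csv(path, sep=_sep_for(path))
    for key in ("onset", "offset"):
        if dialect[key] not in df.columns:
            raise FormatError(f"{path}: required column {dialect[key]!r} not found")
    if len(df) == 0:
        logger.warning("%s: empty %s event table", path, kind)
        return []
    onsets = df[dialect["onset"]].to_numpy(dtype=float)
    offsets = df[dialect["offset"]].to_numpy(dtype=float)
    bad = np.nonzero(offsets <= onsets)[0]
    if bad.size:
        raise ValidationError(
            f"{path}: offset <= onset at row {int(bad[0]) + 1}"
        )
    order = np.argsort(onsets, kind="stable")
    onsets, offsets = onsets[order], offsets[order]
    overlap = np.nonzero(onsets[1:] < offsets[:-1])[0]
    if overlap.size:
        raise ValidationError(
            f"{path}: overlapping {kind} events at sorted rows "
            f"{int(overlap[0]) + 1}/{int(overlap[0]) + 2}"
        )
    return [OcularEvent(kind, float(a), float(b)) for a, b in zip(onsets, offsets)]


def write_events(events: Sequence[OcularEvent], path: str | Path) -> None:
    """Write events as an onset/offset table (seconds, microsecond precision)."""
    df = pd.DataFrame(
        {
            "onset": [ev.onset for ev in events],
            "offset": [ev.offset for ev in events],
            "duration_ms": [ev.duration_ms for ev in events],
        }
    )
    df.to_csv(path, sep=_sep_for(path), index=False, float_format="%.6f")


def read_schedule(path: str | Path) -> list[ScheduleEntry]:
    """Read a trial/phase schedule table (trial, context, order_code, phase,
    start, end) into schedule entries."""
    df = pd.read_csv(path, sep=_sep_for(path))
    required = {"trial", "context", "phase", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: schedule table lacks columns {sorted(missing)}")
    entries: list[ScheduleEntry] = []
    for trial, group in df.groupby("trial", sort=True):
        group = group.set_index("phase")
        windows = tuple(
            PhaseWindow(label, float(group.loc[label, "start"]), float(group.loc[label, "end"]))
            for label in PHASE_LABELS
        )
        order_code = str(group["order_code"].iloc[0]) if "order_code" in group else ""
        ctx = TrialContext(int(trial), str(group["context"].iloc[0]), order_code)
        entries.append((ctx, windows))  # type: ignore[arg-type]
    validate_schedule(entries)
    return entries


def write_schedule(schedule: Sequence[ScheduleEntry], path: str | Path) -> None:
    rows = []
    for ctx, windows in schedule:
        for w in windows:
            rows.append(
                {
                    "trial": ctx.trial_index,
                    "context": ctx.context,
                    "order_code": ctx.order_code,
                    "phase": w.label,
                    "start": w.start,
                    "end": w.end,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(path), index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# Phase segmentation
# ---------------------------------------------------------------------------


def segment_trace(trace: PupilTrace, window: PhaseWindow) -> PupilTrace:
    """Samples with start <= t < end. The window must lie within the span."""
    t0, t1 = trace.span()
    if window.start < t0 - 1e-9 or window.end > t1 + 1e-9 + (t1 - t0) / max(len(trace) - 1, 1):
        raise RangeError(
            f"window [{window.start}, {window.end}) outside recording span [{t0}, {t1}]"
        )
    sel = (trace.timestamps >= window.start) & (trace.timestamps < window.end)
    return PupilTrace(
        trace.timestamps[sel],
        trace.diameter[sel],
        trace.valid[sel],
        trace.interpolated[sel],
        trace.flags[sel],
    )


def segment_events(events: Iterable[OcularEvent], window: PhaseWindow) -> list[OcularEvent]:
    """Events whose ONSET lies in [start, end). Events straddling the phase
    boundary belong to the phase containing their onset."""
    return [ev for ev in events if window.start <= ev.onset < window.end]


def segment_phase(trace_or_events, window: PhaseWindow):
    """Restrict a trace or an event list to one phase window.

    Dispatches on type: traces are cut sample-wise (half-open on timestamps);
    events are assigned by onset.
    """
    if isinstance(trace_or_events, PupilTrace):
        return segment_trace(trace_or_events, window)
    return segment_events(trace_or_events, window)


# ---------------------------------------------------------------------------
# Metrics table
# ---------------------------------------------------------------------------


def validate_metrics_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check column completeness and key uniqueness of a long-format metrics
    table; returns the table with columns in canonical order."""
    missing = set(METRICS_COLUMNS) - set(table.columns)
    if missing:
        raise IntegrityError(f"metrics table lacks columns {sorted(missing)}")
    key = ["participant", "trial", "phase", "measure"]
    dup = table.duplicated(subset=key)
    if dup.any():
        first = table.loc[dup, key].iloc[0].to_dict()
        raise IntegrityError(f"duplicate metrics key {first}")
    return table.loc[:, list(METRICS_COLUMNS)]


def write_metrics_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write the long-format metrics table with a stable column order.

    Raises :class:`IntegrityError` on duplicate (participant, trial, phase,
    measure) keys. Read-back with :func:`read_metrics_table` equals the input
    at the written precision.
    """
    validate_metrics_table(table).to_csv(
        path, sep=_sep_for(path), index=False, float_format="%.9g"
    )


def read_metrics_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep_for(path))
    return validate_metrics_table(df)
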