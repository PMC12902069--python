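"""Per-phase counts and mean durations of fixations and blinks, assembled
into the long-format metrics table.

Events are assigned to phases by ONSET; an event straddling a boundary is
counted once, in the phase containing its onset, and its full duration is
used (duration is a property of the event, not of the window).
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .dilation_peaks import PeakTrain, mean_pupil_size_per_phase, peaks_per_phase
from .pupil_preprocessing import missing_fraction
from .recording_model import (
    METRICS_COLUMNS,
    DyadRecording,
    IntegrityError,
    OcularEvent,
    PhaseWindow,
    PupilTrace,
    validate_metrics_table,
)

logger = logging.getLogger("dyadsync")

__all__ = ["count_events", "mean_event_duration", "build_metrics_table", "MEASURES"]

#: Measures emitted per (participant, trial, phase) cell.
MEASURES = (
    "n_fixations",
    "fixation_duration_ms",
    "n_blinks",
    "blink_duration_ms",
    "n_peaks",
    "mean_pupil_size",
    "missing_fraction",
)


def count_events(events: Iterable[OcularEvent], window: PhaseWindow, kind: str) -> int:
    """Number of events of ``kind`` whose onset lies in [start, end)."""
    return sum(1 for ev in events if ev.kind == kind and window.contains(ev.onset))


def mean_event_duration(events: Iterable[OcularEvent], window: PhaseWindow, kind: str) -> float:
    """Mean duration (ms) of events of ``kind`` with onset in the window;
    NaN (not 0) when the window holds no such event."""
    durations = [ev.duration_ms for ev in events if ev.kind == kind and window.contains(ev.onset)]
    if not durations:
        return float("nan")
    return float(np.mean(durations))


def build_metrics_table(
    dyads: Iterable[DyadRecording],
    preprocessed: Mapping[str, PupilTrace],
    peak_trains: Mapping[str, PeakTrain],
) -> pd.DataFrame:
    """Assemble the complete long-format metrics table.

    ``preprocessed`` and ``peak_trains`` are keyed by participant_id; peaks
    are expected on the full-recording clock. For N dyads the table holds
    N × 2 × 3 trials × 3 phases rows per measure. A missing trace or peak
    train for any participant raises :class:`IntegrityError`.
    """
    rows: list[dict] = []
    gaps: list[str] = []
    for dyad in dyads:
        for member in dyad.members():
            pid = member.participant_id
            trace = preprocessed.get(pid)
            peaks = peak_trains.get(pid)
            if trace is None or peaks is None:
                gaps.append(pid)
                continue
            for ctx, windows in member.schedule:
                for window in windows:
                    frac, _ = missing_fraction(trace, window)
                    values = {
                        "n_fixations": count_events(member.events, window, "fixation"),
                        "fixation_duration_ms": mean_event_duration(
                            member.events, window, "fixation"
                        ),
                        "n_blinks": count_events(member.events, window, "blink"),
                        "blink_duration_ms": mean_event_duration(member.events, window, "blink"),
                        "n_peaks": peaks_per_phase(peaks, window),
                        "mean_pupil_size": mean_pupil_size_per_phase(trace, window),
                        "missing_fraction": frac,
                    }
                    for measure, value in values.items():
                        rows.append(
                            {
                                "dyad": dyad.dyad_id,
                                "participant": pid,
                                "role": member.role,
                                "trial": ctx.trial_index,
                                "context": ctx.context,
                                "phase": window.label,
                                "measure": measure,
                                "value": value,
                            }
                        )
    if gaps:
        raise IntegrityError(f"missing preprocessed trace or peak train for {gaps}")
    table = pd.DataFrame(rows, columns=list(METRICS_COLUMNS))
    return validate_metrics_table(table)
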