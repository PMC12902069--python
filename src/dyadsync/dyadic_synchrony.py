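"""Windowed nearest-event synchronization statistics for dyads.

For each reference event onset (listener by default) the nearest test event
onset (observer) is found and the signed lag ``test - reference`` recorded.
A reference event counts as synchronized when ``|lag| <= half_window``
(±1.5 s for blinks, ±2.5 s for pupil dilation-velocity peaks); the
synchronization percentage of a phase is the share of that phase's reference
events that are synchronized. With an independent Poisson test train of rate
λ the expected percentage is the chance level ``100·(1 − exp(−2·w·λ))``,
which the test suite verifies by simulation.

Conventions (all deliberate, see the methods note): the denominator is the
reference member's events in the phase; nearest-neighbour ties resolve to the
earlier test event (negative lag); matching is non-exclusive; the in-window
comparison is inclusive; and the nearest-neighbour search may cross phase
boundaries for the test train, since windows are anchored on reference onsets
rather than clipped to phases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .recording_model import DyadRecording

logger = logging.getLogger("dyadsync")

__all__ = [
    "SyncConfig",
    "SyncResult",
    "nearest_event_lag",
    "sync_percentage",
    "dyad_sync_table",
    "sync_results_to_frame",
    "sync_cross_correlation",
    "poisson_chance_level",
]

#: Default half-window (s) per modality.
DEFAULT_HALF_WINDOW = {"blink": 1.5, "pupil_peak": 2.5}


@dataclass(frozen=True)
class SyncConfig:
    """Synchrony-statistic parameters."""

    modality: str = "blink"
    half_window: float | None = None  # defaults per modality
    reference_role: str = "listener"
    #: denominator: reference member's phase events ("reference") or both
    #: members' pooled events ("pooled"), for sensitivity analysis.
    denominator: str = "reference"
    #: allow the nearest-neighbour search to see test events across phase
    #: boundaries (windows are anchored on reference onsets).
    cross_phase_test: bool = True

    def __post_init__(self) -> None:
        if self.modality not in DEFAULT_HALF_WINDOW:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.half_window is not None and self.half_window <= 0:
            raise ValueError("half_window must be positive")
        if self.reference_role not in ("listener", "observer"):
            raise ValueError("reference_role must be listener or observer")
        if self.denominator not in ("reference", "pooled"):
            raise ValueError("denominator must be 'reference' or 'pooled'")

    @property
    def window(self) -> float:
        return self.half_window if self.half_window is not None else DEFAULT_HALF_WINDOW[self.modality]


@dataclass
class SyncResult:
    """Synchrony of one dyad × trial × phase cell."""

    dyad_id: str
    trial_index: int
    context: str
    phase: str
    n_reference_events: int
    n_test_events: int
    lags: np.ndarray
    sync_percentage: float  # NaN when no reference events

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)


def nearest_event_lag(reference_onsets: np.ndarray, test_onsets: np.ndarray) -> np.ndarray:
    """Signed lag ``test* - reference`` to the nearest test onset, per
    reference onset.

    Both inputs must be sorted. Equidistant candidates resolve to the earlier
    test event (negative lag). An empty test train yields all-NaN lags.
    """
    reference_onsets = np.asarray(reference_onsets, dtype=float)
    test_onsets = np.asarray(test_onsets, dtype=float)
    if reference_onsets.size == 0:
        return np.empty(0)
    if test_onsets.size == 0:
        return np.full(reference_onsets.size, np.nan)
    pos = np.searchsorted(test_onsets, reference_onsets)
    left = np.clip(pos - 1, 0, test_onsets.size - 1)
    right = np.clip(pos, 0, test_onsets.size - 1)
    dl = np.abs(test_onsets[left] - reference_onsets)
    dr = np.abs(test_onsets[right] - reference_onsets)
    # ties (dl == dr) go to the earlier (left) event
    choose_left = dl <= dr
    nearest = np.where(choose_left, test_onsets[left], test_onsets[right])
    return nearest - reference_onsets


def sync_percentage(
    reference_onsets: np.ndarray,
    test_onsets: np.ndarray,
    half_window: float,
) -> tuple[float, np.ndarray]:
    """Percentage of reference events whose nearest test lag satisfies
    ``|lag| <= half_window``, plus the lag list.

    NaN (never 0 or 100) with a warning when the reference train is empty.
    """
    lags = nearest_event_lag(reference_onsets, test_onsets)
    if lags.size == 0:
        logger.warning("zero reference events: synchronization undefined")
        return float("nan"), lags
    matched = np.abs(lags) <= half_window  # NaN lags compare False
    return float(100.0 * np.count_nonzero(matched) / lags.size), lags


def poisson_chance_level(half_window: float, rate: float) -> float:
    """Expected sync%% against an independent homogeneous Poisson test train:
    ``100·(1 − exp(−2·half_window·rate))``."""
    return 100.0 * (1.0 - np.exp(-2.0 * half_window * rate))


def dyad_sync_table(
    dyads: list[DyadRecording],
    event_times: dict[str, np.ndarray],
    config: SyncConfig = SyncConfig(),
) -> list[SyncResult]:
    """One :class:`SyncResult` per dyad × trial × phase.

    ``event_times`` maps participant_id to that member's sorted event-onset
    times on the recording clock (blink onsets or dilation-peak times,
    matching ``config.modality``). The reference member is
    ``config.reference_role``; phases with zero reference events yield a
    missing (NaN) percentage and are logged.
    """
    results: list[SyncResult] = []
    n_missing = 0
    for dyad in dyads:
        ref_member = getattr(dyad, config.reference_role)
        test_member = dyad.observer if config.reference_role == "listener" else dyad.listener
        ref_all = np.sort(np.asarray(event_times.get(ref_member.participant_id, []), dtype=float))
        test_all = np.sort(np.asarray(event_times.get(test_member.participant_id, []), dtype=float))
        for ctx, windows in dyad.schedule:
            for window in windows:
                in_ref = ref_all[(ref_all >= window.start) & (ref_all < window.end)]
                if config.cross_phase_test:
                    in_test = test_all
                else:
                    in_test = test_all[(test_all >= window.start) & (test_all < window.end)]
                pct, lags = sync_percentage(in_ref, in_test, config.window)
                if config.denominator == "pooled" and np.isfinite(pct):
                    n_test_phase = int(
                        np.count_nonzero((test_all >= window.start) & (test_all < window.end))
                    )
                    denom = in_ref.size + n_test_phase
                    pct = 100.0 * np.count_nonzero(np.abs(lags) <= config.window) / denom if denom else float("nan")
                if not np.isfinite(pct):
                    n_missing += 1
                results.append(
                    SyncResult(
                        dyad_id=dyad.dyad_id,
                        trial_index=ctx.trial_index,
                        context=ctx.context,
                        phase=window.label,
                        n_reference_events=int(in_ref.size),
                        n_test_events=int(
                            np.count_nonzero((test_all >= window.start) & (test_all < window.end))
                        ),
                        lags=lags,
                        sync_percentage=pct,
                    )
                )
    if n_missing:
        logger.info("%d dyad × trial × phase cells had zero reference events", n_missing)
    return results


def sync_results_to_frame(results: list[SyncResult]) -> pd.DataFrame:
    """Flatten sync results into the stats-ready table (lags dropped)."""
    return pd.DataFrame(
        {
            "dyad": [r.dyad_id for r in results],
            "trial": [r.trial_index for r in results],
            "context": [r.context for r in results],
            "phase": [r.phase for r in results],
            "n_ref": [r.n_reference_events for r in results],
            "n_test": [r.n_test_events for r in results],
            "sync_pct": [r.sync_percentage for r in results],
        }
    )


def sync_cross_correlation(
    blink_sync: pd.DataFrame, peak_sync: pd.DataFrame
) -> pd.DataFrame:
    """Spearman rank correlation between blink and pupil-peak synchrony
    across dyads, per phase (two-sided p).

    Per-dyad per-phase values are means over trials. Phases with fewer than
    3 paired dyads yield NaN.
    """
    out = []
    for phase in blink_sync["phase"].unique():
        b = (
            blink_sync[blink_sync["phase"] == phase]
            .groupby("dyad")["sync_pct"]
            .mean()
        )
        p = (
            peak_sync[peak_sync["phase"] == phase]
            .groupby("dyad")["sync_pct"]
            .mean()
        )
        joined = pd.concat([b.rename("blink"), p.rename("pupil")], axis=1).dropna()
        if len(joined) < 3:
            rho, pval = float("nan"), float("nan")
        else:
            rho, pval = spearmanr(joined["blink"], joined["pupil"])
        out.append({"phase": phase, "rho": float(rho), "p": float(pval), "n_dyads": len(joined)})
    return pd.DataFrame(out)
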