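"""Pupil-trace artifact rejection.

The chain, in order: linear reconstruction of blink spans (100 ms before to
150 ms after each blink) and saccade spans (75 ms buffer both sides), removal
of dilation-speed outliers beyond median + 3×MAD, trimming of 50 ms on either
side of data gaps longer than 75 ms, a sparsity filter that discards valid
islands shorter than 50 ms flanked on both sides by gaps longer than 40 ms,
and a per-phase missing-data fraction with a 30% exclusion rule.

Conventions:

* Threshold comparisons are strict (">" = "exceeding"), so a flat trace flags
  nothing and a phase at exactly 30% missing is retained.
* MAD is the unscaled median absolute deviation (no normal-consistency
  factor): the rule is literally median + multiplier × MAD.
* Dilation speed is the two-sided maximum absolute difference quotient over
  valid neighbours, the standard definition in pupillometry preprocessing
  guidelines.
* No stage ever converts an invalid sample back to valid, and no stage alters
  timestamps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields

import numpy as np

from .recording_model import (
    FLAG_EDGE_TRIM,
    FLAG_INTERPOLATED,
    FLAG_MISSING,
    FLAG_SPARSITY,
    FLAG_SPEED_OUTLIER,
    OcularEvent,
    PhaseWindow,
    PupilTrace,
    RangeError,
)

logger = logging.getLogger("dyadsync")

__all__ = [
    "PreprocessConfig",
    "PreprocessReport",
    "InsufficientDataError",
    "interpolate_event_spans",
    "dilation_speed",
    "mad_speed_filter",
    "trim_gap_edges",
    "sparsity_filter",
    "missing_fraction",
    "preprocess_pipeline",
]


class InsufficientDataError(ValueError):
    """Too few valid samples to compute the requested quantity."""


@dataclass(frozen=True)
class PreprocessConfig:
    """Artifact-rejection parameters (field-standard defaults)."""

    blink_pre: float = 100.0  # ms before blink onset
    blink_post: float = 150.0  # ms after blink offset
    saccade_buffer: float = 75.0  # ms both sides of a saccade
    mad_multiplier: float = 3.0
    edge_pad: float = 50.0  # ms trimmed each side of a gap
    edge_min_gap: float = 75.0  # ms; only gaps longer than this are trimmed
    sparsity_max_island: float = 50.0  # ms; islands shorter than this...
    sparsity_flank_gap: float = 40.0  # ...flanked by gaps longer than this
    missing_exclusion_threshold: float = 0.30  # fraction per phase
    # stage switches (the full chain runs unconditionally by default)
    enable_blink_interpolation: bool = True
    enable_saccade_interpolation: bool = True
    enable_mad_filter: bool = True
    enable_edge_trim: bool = True
    enable_sparsity_filter: bool = True

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, float) and v < 0:
                raise ValueError(f"{f.name} must be non-negative")
        if self.mad_multiplier <= 0:
            raise ValueError("mad_multiplier must be positive")
        if not 0 < self.missing_exclusion_threshold <= 1:
            raise ValueError("missing_exclusion_threshold must lie in (0, 1]")


@dataclass
class PreprocessReport:
    """Per-stage sample counts and per-phase missingness of one recording."""

    n_samples: int = 0
    n_missing_input: int = 0
    n_interpolated_blink: int = 0
    n_interpolated_saccade: int = 0
    n_invalidated_unanchored: int = 0
    n_speed_outliers: int = 0
    n_edge_trimmed: int = 0
    n_sparsity_removed: int = 0
    missing_fraction_by_phase: dict[str, float] = field(default_factory=dict)
    excluded_phases: list[str] = field(default_factory=list)

    @property
    def n_invalid_final(self) -> int:
        return (
            self.n_missing_input
            - self.n_interpolated_blink
            - self.n_interpolated_saccade
            + self.n_invalidated_unanchored
            + self.n_speed_outliers
            + self.n_edge_trimmed
            + self.n_sparsity_removed
        )


def _invalidate(trace: PupilTrace, idx: np.ndarray, flag: int) -> int:
    """Mark samples invalid with a provenance flag; returns newly invalid count."""
    newly = idx & trace.valid
    trace.valid[newly] = False
    trace.interpolated[newly] = False
    trace.diameter[newly] = np.nan
    trace.flags[idx] |= flag
    return int(newly.sum())


# ---------------------------------------------------------------------------
# Stage 1-2: event-span interpolation
# ---------------------------------------------------------------------------


def interpolate_event_spans(
    trace: PupilTrace,
    events: list[OcularEvent],
    pre: float,
    post: float,
) -> PupilTrace:
    """Linearly reconstruct padded event spans.

    Samples with ``onset - pre <= t <= offset + post`` (pads in ms) are
    replaced by the line joining the nearest valid samples outside the padded
    span and marked interpolated. Spans without a valid anchor on either side
    (e.g. touching the trace boundary) are invalidated instead — values are
    never extrapolated.
    """
    out = trace.copy()
    t = out.timestamps
    n = len(out)
    for ev in events:
        lo_t, hi_t = ev.onset - pre / 1000.0, ev.offset + post / 1000.0
        span = (t >= lo_t) & (t <= hi_t)
        if not span.any():
            continue
        i0, i1 = np.nonzero(span)[0][[0, -1]]
        left = np.nonzero(out.valid[:i0] & ~span[:i0])[0]
        right_rel = np.nonzero(out.valid[i1 + 1 :])[0]
        if left.size == 0 or right_rel.size == 0:
            logger.warning(
                "event span [%0.3f, %0.3f] has no valid anchor on one side; invalidated",
                lo_t,
                hi_t,
            )
            _invalidate(out, span, FLAG_MISSING)
            continue
        a = int(left[-1])
        b = int(i1 + 1 + right_rel[0])
        ya, yb = out.diameter[a], out.diameter[b]
        out.diameter[span] = ya + (yb - ya) * (t[span] - t[a]) / (t[b] - t[a])
        out.valid[span] = True
        out.interpolated[span] = True
        out.flags[span] |= FLAG_INTERPOLATED
    return out


# ---------------------------------------------------------------------------
# Stage 3: dilation-speed MAD filter
# ---------------------------------------------------------------------------


def dilation_speed(trace: PupilTrace) -> np.ndarray:
    """Two-sided maximum absolute difference quotient per sample (units/s).

    ``speed[i] = max(|d[i]-d[prev]|/(t[i]-t[prev]), |d[next]-d[i]|/(t[next]-t[i]))``
    where prev/next are the nearest *valid* neighbours (invalid samples are
    skipped); the first/last valid samples use their single neighbour.
    Invalid samples get NaN.
    """
    vidx = np.nonzero(trace.valid)[0]
    if vidx.size < 3:
        raise InsufficientDataError(
            f"dilation speed needs >= 3 valid samples, got {vidx.size}"
        )
    tv = trace.timestamps[vidx]
    dv = trace.diameter[vidx]
    quot = np.abs(np.diff(dv)) / np.diff(tv)
    back = np.concatenate([[np.nan], quot])  # speed vs previous valid sample
    fwd = np.concatenate([quot, [np.nan]])  # speed vs next valid sample
    speed_valid = np.fmax(back, fwd)  # fmax ignores the NaN endpoints
    speed = np.full(len(trace), np.nan)
    speed[vidx] = speed_valid
    return speed


def mad_speed_filter(trace: PupilTrace, multiplier: float = 3.0) -> PupilTrace:
    """Invalidate samples whose dilation speed exceeds median + multiplier×MAD.

    MAD is the unscaled median absolute deviation of the speed distribution
    over the trace's valid samples; the comparison is strict, so a degenerate
    flat trace (MAD = 0, all speeds 0) flags nothing.
    """
    out = trace.copy()
    speed = dilation_speed(out)
    finite = np.isfinite(speed)
    med = float(np.median(speed[finite]))
    mad = float(np.median(np.abs(speed[finite] - med)))
    if mad == 0.0:
        logger.warning("speed MAD is zero (degenerate trace); no samples flagged")
        return out
    threshold = med + multiplier * mad
    flag = finite & (speed > threshold)
    n = _invalidate(out, flag, FLAG_SPEED_OUTLIER)
    logger.info("MAD speed filter: %d samples > %.4g units/s invalidated", n, threshold)
    return out


# ---------------------------------------------------------------------------
# Stage 4: gap-edge trimming
# ---------------------------------------------------------------------------


def _invalid_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in ``mask`` as (start, stop) index pairs (half-open)."""
    padded = np.concatenate([[False], mask, [False]])
    edges = np.diff(padded.astype(np.int8))
    starts = np.nonzero(edges == 1)[0]
    stops = np.nonzero(edges == -1)[0]
    return list(zip(starts, stops))


def trim_gap_edges(trace: PupilTrace, pad: float = 50.0, min_gap: float = 75.0) -> PupilTrace:
    """Invalidate ``pad`` ms of data before and after gaps longer than
    ``min_gap`` ms.

    Gap duration is the run length in samples times the nominal sample
    spacing. Samples previously invalidated *by this stage* are not counted
    when locating gaps, which makes the operation idempotent; pads of
    adjacent gaps simply union.
    """
    out = trace.copy()
    t = out.timestamps
    dt = float(np.median(np.diff(t))) if len(out) > 1 else 0.0
    core_invalid = (~out.valid) & ((out.flags & FLAG_EDGE_TRIM) == 0)
    to_trim = np.zeros(len(out), dtype=bool)
    for start, stop in _invalid_runs(core_invalid):
        if (stop - start) * dt * 1000.0 <= min_gap:
            continue
        pad_s = pad / 1000.0 + 1e-9
        before = (t >= t[start] - pad_s) & (t < t[start])
        after = (t > t[stop - 1]) & (t <= t[stop - 1] + pad_s)
        to_trim |= before | after
    n = _invalidate(out, to_trim, FLAG_EDGE_TRIM)
    if n:
        logger.info("gap-edge trimming: %d samples invalidated", n)
    return out


# ---------------------------------------------------------------------------
# Stage 5: sparsity filter
# ---------------------------------------------------------------------------


def sparsity_filter(
    trace: PupilTrace, max_island: float = 50.0, flank_gap: float = 40.0
) -> PupilTrace:
    """Invalidate valid islands shorter than ``max_island`` ms whose BOTH
    flanking gaps are longer than ``flank_gap`` ms.

    Trace boundaries count as infinitely long gaps. All islands are judged
    against the input mask simultaneously, which makes the filter idempotent.
    """
    out = trace.copy()
    dt = float(np.median(np.diff(out.timestamps))) if len(out) > 1 else 0.0
    invalid = ~out.valid
    runs = _invalid_runs(invalid)
    gap_ms = {(s, e): (e - s) * dt * 1000.0 for s, e in runs}
    to_remove = np.zeros(len(out), dtype=bool)
    for start, stop in _invalid_runs(out.valid):  # valid islands
        if (stop - start) * dt * 1000.0 >= max_island:
            continue
        left = np.inf if start == 0 else gap_ms.get(_run_ending_at(runs, start), 0.0)
        right = np.inf if stop == len(out) else gap_ms.get(_run_starting_at(runs, stop), 0.0)
        if left > flank_gap and right > flank_gap:
            to_remove[start:stop] = True
    n = _invalidate(out, to_remove, FLAG_SPARSITY)
    if n:
        logger.info("sparsity filter: %d samples invalidated", n)
    return out


def _run_ending_at(runs: list[tuple[int, int]], idx: int) -> tuple[int, int]:
    for s, e in runs:
        if e == idx:
            return (s, e)
    return (idx, idx)


def _run_starting_at(runs: list[tuple[int, int]], idx: int) -> tuple[int, int]:
    for s, e in runs:
        if s == idx:
            return (s, e)
    return (idx, idx)


# ---------------------------------------------------------------------------
# Missing-data accounting
# ---------------------------------------------------------------------------


def missing_fraction(
    trace: PupilTrace,
    window: PhaseWindow,
    sampling_rate: float | None = None,
    threshold: float = 0.30,
) -> tuple[float, bool]:
    """Fraction of a phase's expected samples that are missing, plus the
    exclusion flag (strictly greater than ``threshold``).

    Interpolated samples count as present; samples absent from the trace
    entirely (e.g. a cropped file) count as missing.
    """
    if window.length <= 0:
        raise RangeError("empty phase window")
    fs = sampling_rate if sampling_rate is not None else trace.sampling_rate
    expected = int(round(window.length * fs))
    sel = (trace.timestamps >= window.start) & (trace.timestamps < window.end)
    n_present = int(np.count_nonzero(trace.valid[sel]))
    frac = float(np.clip((expected - n_present) / expected, 0.0, 1.0))
    return frac, frac > threshold


# ---------------------------------------------------------------------------
# Full chain
# ---------------------------------------------------------------------------


def preprocess_pipeline(
    trace: PupilTrace,
    blink_events: list[OcularEvent],
    saccade_events: list[OcularEvent],
    config: PreprocessConfig = PreprocessConfig(),
    phases: list[PhaseWindow] | None = None,
) -> tuple[PupilTrace, PreprocessReport]:
    """Run the full artifact-rejection chain in order:
    blink interpolation → saccade interpolation → speed-outlier removal →
    gap-edge trimming → sparsity filter.

    The MAD statistics are computed over the whole continuous trace passed in
    (call per trial to scope the filter per trial). If ``phases`` is given,
    the report includes per-phase missing fractions and exclusion flags.
    """
    report = PreprocessReport(n_samples=len(trace), n_missing_input=int((~trace.valid).sum()))
    out = trace
    if config.enable_blink_interpolation:
        before = int(out.interpolated.sum())
        out = interpolate_event_spans(out, blink_events, config.blink_pre, config.blink_post)
        report.n_interpolated_blink = int(out.interpolated.sum()) - before
    if config.enable_saccade_interpolation:
        before = int(out.interpolated.sum())
        out = interpolate_event_spans(
            out, saccade_events, config.saccade_buffer, config.saccade_buffer
        )
        report.n_interpolated_saccade = int(out.interpolated.sum()) - before
    if config.enable_mad_filter:
        before = int(out.valid.sum())
        out = mad_speed_filter(out, config.mad_multiplier)
        report.n_speed_outliers = before - int(out.valid.sum())
    if config.enable_edge_trim:
        before = int(out.valid.sum())
        out = trim_gap_edges(out, config.edge_pad, config.edge_min_gap)
        report.n_edge_trimmed = before - int(out.valid.sum())
    if config.enable_sparsity_filter:
        before = int(out.valid.sum())
        out = sparsity_filter(out, config.sparsity_max_island, config.sparsity_flank_gap)
        report.n_sparsity_removed = before - int(out.valid.sum())
    if phases:
        for window in phases:
            frac, excluded = missing_fraction(
                out, window, threshold=config.missing_exclusion_threshold
            )
            report.missing_fraction_by_phase[f"{window.label}@{window.start:g}"] = frac
            if excluded:
                report.excluded_phases.append(f"{window.label}@{window.start:g}")
    return out, report
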