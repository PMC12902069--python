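"""Synthetic dyadic recordings with known ground truth.

The generator emulates the study design downstream stages expect: two
participants (listener/observer) recorded simultaneously at 200 Hz through
three trials of three consecutive 30-s phases (baseline, audio, silence), one
emotional context per trial in counterbalanced order.

What is emulated, and how:

* **Blink trains** — the listener blinks as a homogeneous Poisson process with
  a 100-ms refractory merge. Each listener blink, with a per-phase coupling
  probability, elicits an observer blink at a truncated-normal lag (±1.5 s);
  independent observer blinks are superposed. The per-phase coupling defaults
  (baseline > silence > audio) mirror the attentional-coupling structure the
  synchrony statistics are designed to detect.
* **Pupil traces** — baseline diameter plus a slow drift, a narrowband
  hippus-like oscillation, event-related dilation kernels (zero until
  ~0.8 s after the event, peaking 2-2.8 s after it), band-limited slow
  measurement noise, and a bounded high-frequency sensor-jitter component.
  The error model is deliberately not white Gaussian: pupil diameter is a
  low-bandwidth physiological signal and video-based pupillometers average
  many pixels per estimate, so sample-to-sample white noise at 200 Hz is not
  a realistic error model — and because a Gaussian-dominated dilation-speed
  distribution has ~5% of its mass beyond median + 3×MAD *whatever its
  scale*, it would defeat any robust-dispersion speed filter by
  construction. Jitter is therefore modeled as a micron-scale bounded
  narrowband oscillation (quantization-like residual of the pupil model
  fit), which gives the speed statistic the compact, artifact-free
  background distribution the filter's design presumes.
* **Sensor artifacts** — missing-data gaps and single-sample speed spikes,
  planted at known locations and recorded in the ground truth.
* **Fixation/saccade streams** — alternating renewal tilings with log-normal
  fixation durations per phase (long fixations on the cross at baseline,
  short exploratory fixations during mutual gaze).

Determinism: identical ``(config, seed)`` produces byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .recording_model import (
    CONTEXT_LABELS,
    PHASE_LABELS,
    DyadRecording,
    OcularEvent,
    ParticipantRecording,
    PhaseWindow,
    PupilTrace,
    RangeError,
    ScheduleEntry,
    TrialContext,
)

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_blink_trains",
    "generate_pupil_trace",
    "generate_fixation_stream",
    "assemble_dyad",
    "generate_dyad_blink_schedule",
    "default_schedule",
    "dilation_kernel",
    "dilation_steepest_rise_offset",
]

#: Minimum separation between blink onsets (physiological refractory merge).
BLINK_REFRACTORY_S = 0.1


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters. Defaults are the study conditions the pipeline
    is validated under; units in field names or comments.

    ``phase_overrides`` maps a phase label to parameter overrides applied when
    generating that phase (currently honoured for the blink-train parameters),
    e.g. per-phase ``coupling_prob`` to build in the baseline > silence >
    audio synchrony ordering.
    """

    seed: int = 0
    # blink point processes (events/s)
    blink_rate_listener: float = 0.28
    blink_rate_observer: float = 0.20
    coupling_prob: float = 0.25
    #: SD of a per-dyad coupling-probability offset shared by all phases —
    #: interpersonal heterogeneity ("some pairs couple strongly, others
    #: barely"), the source of the dyad random-intercept variance downstream.
    coupling_dyad_sd: float = 0.15
    coupling_lag_mean: float = 0.15  # s
    coupling_lag_sd: float = 0.45  # s, truncated to +-1.5 s
    blink_duration_median_ms: float = 150.0
    blink_duration_log_sd: float = 0.3
    # pupil trace
    pupil_baseline: float = 5.1  # mm (device-class assumption; units not asserted)
    drift_amplitude: float = 0.10  # mm
    drift_period: float = 90.0  # s
    hippus_amplitude: float = 0.03  # mm
    hippus_freq_range: tuple[float, float] = (0.15, 0.40)  # Hz
    dilation_event_rate: float = 0.10  # events/s before refractory thinning
    dilation_refractory: float = 2.0  # s min event spacing
    dilation_onset_latency: float = 0.8  # s
    dilation_peak_latency: float = 2.0  # s (within the 2-2.8 s window)
    dilation_amplitude: float = 0.30  # mm
    dilation_shape: float = 6.0  # gamma-kernel shape (rise steepness)
    noise_sd: float = 0.03  # mm, band-limited slow noise
    noise_smoothing_s: float = 0.30  # s, Gaussian smoothing scale of the noise
    #: bounded sensor jitter: total dilation-speed amplitude (mm/s) split over
    #: narrowband components; micron-scale in diameter.
    jitter_slope_amplitude: float = 2.5
    jitter_bands: tuple[tuple[float, float], ...] = ((70.5, 73.5), (89.0, 91.5))
    # artifacts (events/s)
    artifact_gap_rate: float = 0.02
    artifact_gap_duration_range: tuple[float, float] = (0.08, 0.30)  # s
    artifact_spike_rate: float = 0.02
    spike_amplitude: float = 0.30  # mm, i.e. 10x noise_sd by default
    # fixation renewal process
    fixation_mean_ms: Mapping[str, float] = field(
        default_factory=lambda: {"baseline": 2500.0, "audio": 800.0, "silence": 850.0}
    )
    fixation_log_sd: float = 0.4
    saccade_duration_ms: float = 30.0
    # design
    sampling_rate: float = 200.0  # Hz
    phase_length: float = 30.0  # s
    n_trials: int = 3
    context_order: tuple[str, ...] | None = None  # None: counterbalanced by seed
    phase_overrides: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "baseline": {"coupling_prob": 0.40},
            "audio": {"coupling_prob": 0.10},
            "silence": {"coupling_prob": 0.25},
        }
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.coupling_prob <= 1.0:
            raise ValueError("coupling_prob must lie in [0, 1]")
        for name in (
            "blink_rate_listener",
            "blink_rate_observer",
            "dilation_event_rate",
            "artifact_gap_rate",
            "artifact_spike_rate",
            "noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.sampling_rate <= 0 or self.phase_length <= 0 or self.n_trials < 1:
            raise ValueError("sampling_rate, phase_length and n_trials must be positive")

    def for_phase(self, phase: str) -> "SyntheticConfig":
        """Config with this phase's parameter overrides applied."""
        overrides = dict(self.phase_overrides.get(phase, {}))
        return replace(self, **overrides) if overrides else self


@dataclass
class GroundTruth:
    """Planted structure of a synthetic recording, keyed by role."""

    blink_onsets: dict[str, np.ndarray] = field(default_factory=dict)
    blink_coupled: dict[str, np.ndarray] = field(default_factory=dict)
    dilation_events: dict[str, np.ndarray] = field(default_factory=dict)
    artifact_gaps: dict[str, list[tuple[float, float]]] = field(default_factory=dict)
    artifact_spikes: dict[str, np.ndarray] = field(default_factory=dict)

    def merge(self, other: "GroundTruth") -> None:
        for attr in ("blink_onsets", "blink_coupled", "dilation_events", "artifact_spikes"):
            for role, val in getattr(other, attr).items():
                store = getattr(self, attr)
                if role in store:
                    store[role] = np.concatenate([store[role], val])
                else:
                    store[role] = val
        for role, spans in other.artifact_gaps.items():
            self.artifact_gaps.setdefault(role, []).extend(spans)


# ---------------------------------------------------------------------------
# Blink point processes
# ---------------------------------------------------------------------------


def _poisson_onsets(rate: float, duration: float, rng: np.random.Generator) -> np.ndarray:
    n = rng.poisson(rate * duration)
    return np.sort(rng.uniform(0.0, duration, size=n))


def _enforce_refractory(onsets: np.ndarray, labels: np.ndarray | None = None):
    """Merge onsets closer than the refractory period, keeping the earlier one."""
    keep: list[int] = []
    last = -np.inf
    for i, t in enumerate(onsets):
        if t - last > BLINK_REFRACTORY_S:
            keep.append(i)
            last = t
    kept = onsets[keep]
    return (kept, labels[keep]) if labels is not None else (kept, None)


def generate_blink_trains(
    config: SyntheticConfig,
    duration: float,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Generate coupled listener/observer blink-onset trains on [0, duration).

    The listener train is homogeneous Poisson at ``blink_rate_listener``. Each
    listener onset independently, with probability ``coupling_prob``, spawns an
    observer onset at a Normal(``coupling_lag_mean``, ``coupling_lag_sd``) lag
    truncated to ±1.5 s; independent observer onsets at
    ``blink_rate_observer`` are superposed. Both trains are sorted and onsets
    closer than 100 ms are merged (earlier kept).
    """
    if duration <= 0:
        raise RangeError("duration must be positive")
    rng = np.random.default_rng(config.seed) if rng is None else rng

    listener = _poisson_onsets(config.blink_rate_listener, duration, rng)
    listener, _ = _enforce_refractory(listener)

    coupled_mask = rng.uniform(size=listener.size) < config.coupling_prob
    if config.coupling_lag_sd > 0:
        # truncated normal via rejection (bounded at +-1.5 s)
        lags = np.empty(int(coupled_mask.sum()))
        for i in range(lags.size):
            while True:
                lag = rng.normal(config.coupling_lag_mean, config.coupling_lag_sd)
                if abs(lag) <= 1.5:
                    lags[i] = lag
                    break
    else:
        lags = np.full(int(coupled_mask.sum()), config.coupling_lag_mean)
    coupled = listener[coupled_mask] + lags
    independent = _poisson_onsets(config.blink_rate_observer, duration, rng)

    observer = np.concatenate([coupled, independent])
    labels = np.concatenate(
        [np.ones(coupled.size, dtype=bool), np.zeros(independent.size, dtype=bool)]
    )
    inside = (observer >= 0.0) & (observer < duration)
    observer, labels = observer[inside], labels[inside]
    order = np.argsort(observer, kind="stable")
    observer, labels = _enforce_refractory(observer[order], labels[order])

    truth = GroundTruth(
        blink_onsets={"listener": listener, "observer": observer},
        blink_coupled={
            "listener": coupled_mask,
            "observer": labels,
        },
    )
    return listener, observer, truth


# ---------------------------------------------------------------------------
# Pupil traces
# ---------------------------------------------------------------------------


def dilation_kernel(config: SyntheticConfig, tau: np.ndarray) -> np.ndarray:
    """Event-related dilation kernel evaluated at lags ``tau`` (s post event).

    Zero before ``dilation_onset_latency``; a gamma-shaped rise peaking at
    ``dilation_amplitude`` at ``dilation_peak_latency``; smooth decay after.
    Shape: ``A * x**a * exp(a*(1-x))`` with ``x`` the rescaled time since
    onset latency and ``a = dilation_shape``.
    """
    tau = np.asarray(tau, dtype=float)
    rise = config.dilation_peak_latency - config.dilation_onset_latency
    x = (tau - config.dilation_onset_latency) / rise
    out = np.zeros_like(x)
    pos = x > 0
    a = config.dilation_shape
    out[pos] = config.dilation_amplitude * x[pos] ** a * np.exp(a * (1.0 - x[pos]))
    return out


def dilation_steepest_rise_offset(config: SyntheticConfig) -> float:
    """Lag (s post event) of the kernel's maximum slope, in closed form.

    For the gamma kernel the derivative peaks at ``x = 1 - 1/sqrt(a)``.
    """
    rise = config.dilation_peak_latency - config.dilation_onset_latency
    return config.dilation_onset_latency + rise * (1.0 - 1.0 / np.sqrt(config.dilation_shape))


def generate_dilation_events(
    config: SyntheticConfig, duration: float, rng: np.random.Generator
) -> np.ndarray:
    """Hardcore Poisson dilation-event times: Poisson at ``dilation_event_rate``
    thinned to a minimum separation of ``dilation_refractory`` seconds."""
    onsets = _poisson_onsets(config.dilation_event_rate, duration, rng)
    keep: list[float] = []
    last = -np.inf
    for t in onsets:
        if t - last >= config.dilation_refractory:
            keep.append(t)
            last = t
    return np.asarray(keep)


def _band_limited_noise(
    n: int, fs: float, sd: float, smoothing_s: float, rng: np.random.Generator
) -> np.ndarray:
    if sd == 0 or n == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    smooth = gaussian_filter1d(white, sigma=max(smoothing_s * fs, 1e-9), mode="reflect")
    s = smooth.std()
    return smooth * (sd / s) if s > 0 else np.zeros(n)


def generate_pupil_trace(
    config: SyntheticConfig,
    duration: float,
    event_times: Sequence[float] | np.ndarray,
    rng: np.random.Generator | None = None,
    role: str = "participant",
    inject_artifacts: bool = True,
    blink_spans: Sequence[tuple[float, float]] = (),
) -> tuple[PupilTrace, GroundTruth]:
    """Synthesize a pupil trace with dilation events and planted artifacts.

    The noiseless trace is ``pupil_baseline`` + slow sinusoidal drift +
    hippus oscillation + the sum of dilation kernels at ``event_times``;
    band-limited Gaussian noise is added, then blink gaps (``blink_spans``,
    samples invalidated as a device would during a blink), missing-data gaps
    and single-sample speed spikes are injected. Planted gaps and spikes are
    recorded in the returned :class:`GroundTruth` under ``role``.
    """
    if duration <= 0:
        raise RangeError("duration must be positive")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    fs = config.sampling_rate
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    diameter = np.full(n, config.pupil_baseline)
    if config.drift_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi)
        diameter += config.drift_amplitude * np.sin(2 * np.pi * t / config.drift_period + phase)
    if config.hippus_amplitude > 0:
        f = rng.uniform(*config.hippus_freq_range)
        phase = rng.uniform(0, 2 * np.pi)
        diameter += config.hippus_amplitude * np.sin(2 * np.pi * f * t + phase)
    for ev in np.asarray(event_times, dtype=float):
        lo = int(np.ceil((ev + config.dilation_onset_latency) * fs))
        hi = min(n, lo + int(10.0 * fs))  # kernel support comfortably covered
        if lo >= n:
            continue
        lo = max(lo, 0)
        diameter[lo:hi] += dilation_kernel(config, t[lo:hi] - ev)
    diameter += _band_limited_noise(n, fs, config.noise_sd, config.noise_smoothing_s, rng)
    if config.jitter_slope_amplitude > 0 and config.jitter_bands:
        nb = len(config.jitter_bands)
        for band in config.jitter_bands:
            fj = rng.uniform(*band)
            amp = (config.jitter_slope_amplitude / nb) / (2 * np.pi * fj)
            diameter += amp * np.sin(2 * np.pi * fj * t + rng.uniform(0, 2 * np.pi))

    valid = np.ones(n, dtype=bool)
    for a, b in blink_spans:
        valid[(t >= a) & (t <= b)] = False

    truth = GroundTruth(dilation_events={role: np.asarray(event_times, dtype=float)})
    gaps: list[tuple[float, float]] = []
    spikes: list[float] = []
    if inject_artifacts:
        for start in _poisson_onsets(config.artifact_gap_rate, duration, rng):
            length = rng.uniform(*config.artifact_gap_duration_range)
            sel = (t >= start) & (t < start + length)
            if sel.any() and valid[sel].all():  # avoid piling onto blink gaps
                valid[sel] = False
                gaps.append((float(start), float(min(start + length, duration))))
        for st in _poisson_onsets(config.artifact_spike_rate, duration, rng):
            i = int(round(st * fs))
            if 0 <= i < n and valid[i]:
                diameter[i] += config.spike_amplitude * (1 if rng.uniform() < 0.5 else -1)
                spikes.append(float(t[i]))
    truth.artifact_gaps[role] = gaps
    truth.artifact_spikes[role] = np.asarray(spikes)

    diameter = np.where(valid, diameter, np.nan)
    return PupilTrace(t, diameter, valid), truth


# ---------------------------------------------------------------------------
# Fixation/saccade renewal process
# ---------------------------------------------------------------------------


def generate_fixation_stream(
    config: SyntheticConfig,
    window: PhaseWindow,
    rng: np.random.Generator,
) -> tuple[list[OcularEvent], list[OcularEvent]]:
    """Alternating fixation/saccade tiling of one phase window.

    Fixation durations are log-normal with a per-phase mean; saccades are
    short fixed-duration gaps between fixations.
    """
    mean_ms = float(config.fixation_mean_ms[window.label])
    sigma = config.fixation_log_sd
    mu = np.log(mean_ms / 1000.0) - sigma**2 / 2.0
    sacc = config.saccade_duration_ms / 1000.0
    fixations: list[OcularEvent] = []
    saccades: list[OcularEvent] = []
    t = window.start
    while t < window.end - 1e-9:
        dur = float(rng.lognormal(mu, sigma))
        end = min(t + dur, window.end - 1e-6)
        if end <= t:
            break
        fixations.append(OcularEvent("fixation", t, end))
        t = end
        if t >= window.end - 1e-9:
            break
        s_end = min(t + sacc, window.end - 1e-6)
        if s_end > t:
            saccades.append(OcularEvent("saccade", t, s_end))
        t = s_end + 1e-6
    return fixations, saccades


# ---------------------------------------------------------------------------
# Dyad assembly
# ---------------------------------------------------------------------------


def default_schedule(config: SyntheticConfig, rng: np.random.Generator) -> list[ScheduleEntry]:
    if config.context_order is not None:
        contexts = list(config.context_order)
    else:
        contexts = list(rng.permutation(CONTEXT_LABELS))
    entries: list[ScheduleEntry] = []
    trial_len = 3 * config.phase_length
    for i in range(config.n_trials):
        start = i * trial_len
        windows = tuple(
            PhaseWindow(label, start + j * config.phase_length, start + (j + 1) * config.phase_length)
            for j, label in enumerate(PHASE_LABELS)
        )
        order_code = "".join(c[0].upper() for c in contexts)
        ctx = TrialContext(i + 1, contexts[i % len(contexts)], order_code)
        entries.append((ctx, windows))  # type: ignore[arg-type]
    return entries


def _blink_events(
    onsets: np.ndarray, config: SyntheticConfig, rng: np.random.Generator, t_max: float
) -> list[OcularEvent]:
    events: list[OcularEvent] = []
    mu = np.log(config.blink_duration_median_ms / 1000.0)
    durations = rng.lognormal(mu, config.blink_duration_log_sd, size=onsets.size)
    for i, onset in enumerate(onsets):
        limit = onsets[i + 1] - 0.01 if i + 1 < onsets.size else t_max
        offset = min(onset + durations[i], limit, t_max)
        if offset > onset:
            events.append(OcularEvent("blink", float(onset), float(offset)))
    return events


def generate_dyad_blink_schedule(
    config: SyntheticConfig,
    rng: np.random.Generator,
    schedule: Sequence[ScheduleEntry],
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Blink trains for a whole dyad schedule, phase by phase.

    Each phase is generated with its parameter overrides (per-phase coupling)
    plus a dyad-level coupling offset drawn once — the interpersonal
    heterogeneity that produces the dyad random-intercept variance
    downstream. Returns (onsets, coupled-labels) keyed by role, on the
    recording clock.
    """
    dyad_offset = rng.normal(0.0, config.coupling_dyad_sd) if config.coupling_dyad_sd > 0 else 0.0
    onsets: dict[str, list[np.ndarray]] = {"listener": [], "observer": []}
    coupled: dict[str, list[np.ndarray]] = {"listener": [], "observer": []}
    for ctx, windows in schedule:
        for window in windows:
            phase_cfg = config.for_phase(window.label)
            phase_cfg = replace(
                phase_cfg,
                coupling_prob=float(np.clip(phase_cfg.coupling_prob + dyad_offset, 0.0, 1.0)),
            )
            lst, obs, truth = generate_blink_trains(phase_cfg, window.length, rng)
            onsets["listener"].append(lst + window.start)
            onsets["observer"].append(obs + window.start)
            coupled["listener"].append(truth.blink_coupled["listener"])
            coupled["observer"].append(truth.blink_coupled["observer"])
    return (
        {r: np.concatenate(v) if v else np.empty(0) for r, v in onsets.items()},
        {r: np.concatenate(v) if v else np.empty(0, bool) for r, v in coupled.items()},
    )


def assemble_dyad(
    config: SyntheticConfig, dyad_id: str = "dyad01"
) -> tuple[DyadRecording, GroundTruth]:
    """Generate a complete synthetic dyad: traces, events, schedule, truth.

    Per phase, blink trains are generated with that phase's parameter
    overrides (so per-phase coupling probabilities shape the planted
    synchrony). Dilation events are independent hardcore Poisson processes per
    member over the whole task; artifacts are injected per member.
    """
    rng = np.random.default_rng(config.seed)
    schedule = default_schedule(config, rng)
    total = config.n_trials * 3 * config.phase_length
    blink_onsets, blink_coupled = generate_dyad_blink_schedule(config, rng, schedule)

    truth = GroundTruth()
    members: dict[str, ParticipantRecording] = {}
    for role in ("listener", "observer"):
        onsets = blink_onsets[role]
        truth.blink_onsets[role] = onsets
        truth.blink_coupled[role] = blink_coupled[role]

        blinks = _blink_events(onsets, config, rng, total)
        dil_events = generate_dilation_events(config, total, rng)
        trace, trace_truth = generate_pupil_trace(
            config,
            total,
            dil_events,
            rng=rng,
            role=role,
            blink_spans=[(ev.onset, ev.offset) for ev in blinks],
        )
        truth.merge(trace_truth)

        fixations: list[OcularEvent] = []
        saccades: list[OcularEvent] = []
        for ctx, windows in schedule:
            for window in windows:
                fx, sc = generate_fixation_stream(config, window, rng)
                fixations.extend(fx)
                saccades.extend(sc)

        t_max = float(trace.timestamps[-1])
        events = [ev for ev in blinks + fixations + saccades if ev.onset <= t_max]
        members[role] = ParticipantRecording(
            participant_id=f"{dyad_id}_{role}",
            role=role,
            trace=trace,
            events=events,
            schedule=schedule,
        )

    dyad = DyadRecording(dyad_id, members["listener"], members["observer"])
    return dyad, truth
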