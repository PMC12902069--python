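"""Artifact-rejection chain: interpolation, MAD speed filter, trimming,
sparsity, missing-data accounting."""

import numpy as np
import pytest

from dyadsync.pupil_preprocessing import (
    InsufficientDataError,
    PreprocessConfig,
    dilation_speed,
    interpolate_event_spans,
    mad_speed_filter,
    missing_fraction,
    preprocess_pipeline,
    sparsity_filter,
    trim_gap_edges,
)
from dyadsync.recording_model import OcularEvent, PhaseWindow, PupilTrace

from conftest import random_masked_trace

FS = 200.0


def make_trace(diam, valid=None):
    diam = np.asarray(diam, dtype=float)
    t = np.arange(diam.size) / FS
    if valid is None:
        valid = np.isfinite(diam)
    return PupilTrace(t, diam, valid)


class TestInterpolation:
    def test_linear_signal_reconstructed_exactly(self, ramp_trace):
        blink = OcularEvent("blink", 2.0, 2.2)
        out = interpolate_event_spans(ramp_trace, [blink], pre=100, post=150)
        span = (out.timestamps >= 1.9) & (out.timestamps <= 2.35)
        np.testing.assert_allclose(
            out.diameter[span], 4.0 + 0.1 * out.timestamps[span], atol=1e-12
        )
        assert out.interpolated[span].all()
        assert not out.interpolated[~span].any()

    def test_empty_event_list_is_identity(self, ramp_trace):
        out = interpolate_event_spans(ramp_trace, [], pre=100, post=150)
        np.testing.assert_array_equal(out.diameter, ramp_trace.diameter)
        assert not out.interpolated.any()

    def test_span_at_boundary_invalidated_not_extrapolated(self, ramp_trace):
        blink = OcularEvent("blink", 0.0, 0.2)
        out = interpolate_event_spans(ramp_trace, [blink], pre=100, post=150)
        span = out.timestamps <= 0.35
        assert (~out.valid[span]).all()
        assert np.isnan(out.diameter[span]).all()


class TestDilationSpeed:
    def test_constant_trace_all_zero(self):
        sp = dilation_speed(make_trace(np.full(100, 5.0)))
        np.testing.assert_allclose(sp, 0.0)

    def test_step_speeds(self):
        sp = dilation_speed(make_trace([5.0, 5.0, 6.0, 6.0]))
        np.testing.assert_allclose(sp, [0.0, 200.0, 200.0, 0.0])

    def test_requires_three_valid_samples(self):
        with pytest.raises(InsufficientDataError):
            dilation_speed(make_trace([5.0, np.nan, np.nan, 5.0]))

    def test_matches_bruteforce_over_random_masks(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            trace = random_masked_trace(rng, n=120)
            sp = dilation_speed(trace)
            vidx = np.nonzero(trace.valid)[0]
            for j, i in enumerate(vidx):
                cands = []
                if j > 0:
                    a = vidx[j - 1]
                    cands.append(
                        abs(trace.diameter[i] - trace.diameter[a])
                        / (trace.timestamps[i] - trace.timestamps[a])
                    )
                if j < vidx.size - 1:
                    b = vidx[j + 1]
                    cands.append(
                        abs(trace.diameter[b] - trace.diameter[i])
                        / (trace.timestamps[b] - trace.timestamps[i])
                    )
                assert sp[i] == pytest.approx(max(cands), rel=1e-12)
            assert np.isnan(sp[~trace.valid]).all()


class TestMadFilter:
    def test_flat_trace_flags_nothing(self, caplog):
        trace = make_trace(np.full(100, 5.0))
        with caplog.at_level("WARNING", logger="dyadsync"):
            out = mad_speed_filter(trace)
        assert out.valid.all()
        assert "MAD is zero" in caplog.text

    def test_planted_spike_flagged_exactly(self):
        t = np.arange(2000) / FS
        d = 5.0 + 0.2 * np.sin(2 * np.pi * 0.3 * t)
        d[700] += 10.0
        out = mad_speed_filter(PupilTrace(t, d, np.ones(t.size, bool)), multiplier=3.0)
        flagged = set(np.nonzero(~out.valid)[0])
        # the spike sample and its two neighbours carry the extreme speed
        assert 700 in flagged
        assert flagged <= {699, 700, 701}

    def test_matches_bruteforce_threshold(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            trace = random_masked_trace(rng, n=150)
            out = mad_speed_filter(trace, multiplier=3.0)
            sp = dilation_speed(trace)
            fin = np.isfinite(sp)
            med = np.median(sp[fin])
            mad = np.median(np.abs(sp[fin] - med))
            if mad == 0:
                expected = np.zeros(len(trace), bool)
            else:
                expected = fin & (sp > med + 3.0 * mad)
            np.testing.assert_array_equal(~out.valid, ~trace.valid | expected)


class TestTrimGapEdges:
    def test_pads_around_long_gap(self):
        valid = np.ones(400, bool)
        valid[100:120] = False  # 100 ms gap
        d = np.where(valid, 5.0, np.nan)
        out = trim_gap_edges(make_trace(d, valid), pad=50, min_gap=75)
        assert (~out.valid[90:130]).all()
        assert out.valid[:90].all() and out.valid[130:].all()

    def test_short_gap_untouched(self):
        valid = np.ones(400, bool)
        valid[100:112] = False  # 60 ms
        d = np.where(valid, 5.0, np.nan)
        out = trim_gap_edges(make_trace(d, valid), pad=50, min_gap=75)
        np.testing.assert_array_equal(out.valid, valid)

    def test_overlapping_pads_union_and_idempotent(self):
        valid = np.ones(400, bool)
        valid[100:120] = False
        valid[128:148] = False  # 40 ms apart: pads overlap
        d = np.where(valid, 5.0, np.nan)
        trace = make_trace(d, valid)
        once = trim_gap_edges(trace, pad=50, min_gap=75)
        twice = trim_gap_edges(once, pad=50, min_gap=75)
        np.testing.assert_array_equal(once.valid, twice.valid)
        assert (~once.valid[90:158]).all()


class TestSparsityFilter:
    @staticmethod
    def _mask_trace(valid):
        valid = np.asarray(valid, bool)
        return make_trace(np.where(valid, 5.0, np.nan), valid)

    def test_island_between_long_gaps_removed(self):
        valid = np.r_[
            np.ones(50, bool), np.zeros(10, bool), np.ones(8, bool), np.zeros(10, bool), np.ones(50, bool)
        ]  # 40 ms island between two 50 ms gaps
        out = sparsity_filter(self._mask_trace(valid), max_island=50, flank_gap=40)
        assert (~out.valid[60:68]).all()
        assert out.valid[:50].all() and out.valid[78:].all()

    def test_island_kept_when_one_flank_short(self):
        valid = np.r_[
            np.ones(50, bool), np.zeros(6, bool), np.ones(8, bool), np.zeros(10, bool), np.ones(50, bool)
        ]  # left flank 30 ms only
        out = sparsity_filter(self._mask_trace(valid), max_island=50, flank_gap=40)
        assert out.valid[56:64].all()

    def test_boundary_counts_as_infinite_gap(self):
        valid = np.r_[np.ones(8, bool), np.zeros(10, bool), np.ones(100, bool)]
        out = sparsity_filter(self._mask_trace(valid), max_island=50, flank_gap=40)
        assert (~out.valid[:8]).all()

    def test_matches_bruteforce_run_scan_and_idempotent(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = 300
            valid = rng.uniform(size=n) > 0.25
            valid[rng.integers(0, n, 5)] = True
            trace = self._mask_trace(valid)
            out = sparsity_filter(trace, max_island=50, flank_gap=40)
            # brute force: scan maximal valid runs
            expected = valid.copy()
            i = 0
            dt_ms = 5.0
            while i < n:
                if valid[i]:
                    j = i
                    while j < n and valid[j]:
                        j += 1
                    length = (j - i) * dt_ms
                    li = i
                    while li > 0 and not valid[li - 1]:
                        li -= 1
                    left = np.inf if li == 0 else (i - li) * dt_ms
                    rj = j
                    while rj < n and not valid[rj]:
                        rj += 1
                    right = np.inf if rj == n else (rj - j) * dt_ms
                    if length < 50 and left > 40 and right > 40:
                        expected[i:j] = False
                    i = j
                else:
                    i += 1
            np.testing.assert_array_equal(out.valid, expected)
            again = sparsity_filter(out, max_island=50, flank_gap=40)
            np.testing.assert_array_equal(again.valid, out.valid)


class TestMissingFraction:
    def test_fully_valid_phase(self):
        trace = make_trace(np.full(6000, 5.0))
        frac, excluded = missing_fraction(trace, PhaseWindow("baseline", 0.0, 30.0))
        assert frac == 0.0 and not excluded

    def test_exactly_thirty_percent_not_excluded(self):
        valid = np.ones(6000, bool)
        valid[:1800] = False  # 9 s of 30 s
        trace = make_trace(np.where(valid, 5.0, np.nan), valid)
        frac, excluded = missing_fraction(trace, PhaseWindow("baseline", 0.0, 30.0))
        assert frac == pytest.approx(0.30)
        assert not excluded  # strict >

    def test_interpolated_samples_count_as_present(self, ramp_trace):
        out = interpolate_event_spans(ramp_trace, [OcularEvent("blink", 2.0, 2.2)], 100, 150)
        frac, _ = missing_fraction(out, PhaseWindow("baseline", 0.0, 10.0), sampling_rate=FS)
        assert frac == 0.0


class TestPipeline:
    def test_defaults_are_published_parameters(self):
        cfg = PreprocessConfig()
        assert (cfg.blink_pre, cfg.blink_post) == (100.0, 150.0)
        assert cfg.saccade_buffer == 75.0
        assert cfg.mad_multiplier == 3.0
        assert (cfg.edge_pad, cfg.edge_min_gap) == (50.0, 75.0)
        assert (cfg.sparsity_max_island, cfg.sparsity_flank_gap) == (50.0, 40.0)
        assert cfg.missing_exclusion_threshold == 0.30

    def test_clean_trace_only_changes_in_blink_spans(self, ramp_trace):
        blink = OcularEvent("blink", 4.0, 4.25)
        out, report = preprocess_pipeline(ramp_trace, [blink], [], PreprocessConfig())
        outside = ~out.interpolated & out.valid
        np.testing.assert_array_equal(out.diameter[outside], ramp_trace.diameter[outside])
        assert report.n_interpolated_blink > 0
        assert report.n_sparsity_removed == 0

    def test_monotone_invalidation_and_fixed_timestamps(self, dyad_and_truth):
        dyad, _ = dyad_and_truth
        member = dyad.listener
        trace = member.trace
        sel = trace.timestamps < 90.0
        sub = PupilTrace(
            trace.timestamps[sel], trace.diameter[sel], trace.valid[sel]
        )
        blinks = [e for e in member.events_of("blink") if e.onset < 90.0]
        saccades = [e for e in member.events_of("saccade") if e.onset < 90.0]
        cfg = PreprocessConfig()
        stage_in = interpolate_event_spans(sub, blinks, cfg.blink_pre, cfg.blink_post)
        stage_in = interpolate_event_spans(stage_in, saccades, cfg.saccade_buffer, cfg.saccade_buffer)
        for stage in (
            lambda tr: mad_speed_filter(tr, cfg.mad_multiplier),
            lambda tr: trim_gap_edges(tr, cfg.edge_pad, cfg.edge_min_gap),
            lambda tr: sparsity_filter(tr, cfg.sparsity_max_island, cfg.sparsity_flank_gap),
        ):
            stage_out = stage(stage_in)
            # invalid samples never resurrect, timestamps never change
            assert not (stage_out.valid & ~stage_in.valid).any()
            np.testing.assert_array_equal(stage_out.timestamps, stage_in.timestamps)
            stage_in = stage_out

    def test_stage_switches_disable_stages(self, ramp_trace):
        cfg = PreprocessConfig(
            enable_blink_interpolation=False,
            enable_saccade_interpolation=False,
            enable_mad_filter=False,
            enable_edge_trim=False,
            enable_sparsity_filter=False,
        )
        out, report = preprocess_pipeline(ramp_trace, [OcularEvent("blink", 1.0, 1.2)], [], cfg)
        np.testing.assert_array_equal(out.diameter, ramp_trace.diameter)
        assert report.n_interpolated_blink == 0
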