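"""Phase segmentation of intensity traces and event-timing operators."""

import numpy as np
import pytest

from hsafm_cme.detection import PitDetection
from hsafm_cme.lifecycle import (ChannelAbsentError, IntensityTrace,
                                 NoSignalError, detect_event_times,
                                 relative_timing, segment_phases,
                                 smooth_3frame)
from hsafm_cme.tracking import PitTrack


def trace_of(values, sigma=0.0):
    return IntensityTrace(event_id=0, channel="clathrin",
                          values=np.asarray(values, dtype=float),
                          frame_interval_s=10.0, noise_sigma=sigma)


def trapezoid():
    """Rise +0.2/frame x 5, flat x 6, fall -0.2/frame x 5."""
    rise = np.arange(1, 6) * 0.2
    flat = np.ones(6)
    fall = np.arange(4, -1, -1) * 0.2
    return np.concatenate([[0.0], rise, flat, fall])


class TestSegmentation:
    def test_trapezoid_stable_covers_flat_interior(self):
        seg = segment_phases(trace_of(trapezoid()))
        assert not seg.stable_empty
        # the flat run occupies indices 6..11; smoothing blurs the edges,
        # the interior must be inside the stable phase
        assert seg.stable_start <= 7
        assert seg.stable_end >= 10

    def test_slow_ramp_is_all_stable(self):
        """+0.08/frame is inside the [-0.05, +0.1] band, so a pure ramp
        qualifies as stable over its whole interior."""
        ramp = np.arange(13) * 0.08
        seg = segment_phases(trace_of(ramp / ramp.max()))
        assert not seg.stable_empty
        assert seg.stable_end - seg.stable_start >= 8

    def test_sharp_triangle_splits_at_peak(self):
        tri = np.concatenate([np.arange(4) / 3.0, np.arange(2, -1, -1) / 3.0])
        seg = segment_phases(trace_of(tri))
        assert seg.stable_empty
        assert seg.stable_start == seg.stable_end == int(np.argmax(
            smooth_3frame(tri / tri.max())))

    def test_all_zero_trace_raises(self):
        with pytest.raises(NoSignalError):
            segment_phases(trace_of(np.zeros(10)))

    def test_too_short_trace_raises(self):
        with pytest.raises(ValueError):
            segment_phases(trace_of([0, 1, 0]))

    def test_durations_partition_signal_interval(self):
        seg = segment_phases(trace_of(trapezoid()))
        total = (seg.signal_end - seg.signal_start) * 10.0
        assert seg.growing_s + seg.stable_s + seg.closing_s == \
            pytest.approx(total)

    def test_invariant_to_positive_rescaling(self):
        base = trapezoid()
        a = segment_phases(trace_of(base))
        b = segment_phases(trace_of(base * 731.0))
        assert (a.signal_start, a.stable_start, a.stable_end, a.signal_end) \
            == (b.signal_start, b.stable_start, b.stable_end, b.signal_end)

    def test_widening_band_never_shrinks_qualifying_set(self):
        vals = trace_of(trapezoid())
        narrow = segment_phases(vals, slope_band=(-0.05, 0.1))
        wide = segment_phases(vals, slope_band=(-0.10, 0.2))
        assert wide.stable_s >= narrow.stable_s


class TestPhaseRecoveryOnGeneratorTraces:
    """Criterion: boundaries recovered within 1 frame at zero noise and
    within 2 frames at the default photon budget for >= 90% of events."""

    @staticmethod
    def _cohort(rel_noise, n=150):
        from hsafm_cme.events import sample_events
        from hsafm_cme.traces import synthesize_trace
        from conftest import in_field_config

        cfg = in_field_config(n_frames=80, n_events=1)
        noise_rng = np.random.default_rng(2)
        errs = []
        seed = 0
        while len(errs) < n and seed < 4 * n:
            ev = sample_events(cfg.replace(seed=seed),
                               np.random.default_rng(seed))[0]
            seed += 1
            if ev.identity != "CCP" or ev.final_closure_frame is None:
                continue
            clean = synthesize_trace(ev, "clathrin", cfg)
            if clean.max() <= 0 or (clean > 0.02).sum() < 6:
                continue
            truth = segment_phases(trace_of(clean))
            noisy = np.clip(clean + noise_rng.normal(0, rel_noise, clean.shape),
                            0, None) if rel_noise else clean
            got = segment_phases(trace_of(noisy, sigma=rel_noise))
            errs.append(max(
                abs(got.signal_start - truth.signal_start),
                abs(got.stable_start - truth.stable_start),
                abs(got.stable_end - truth.stable_end),
                abs(got.signal_end - truth.signal_end)))
        return np.array(errs)

    def test_zero_noise_within_one_frame(self):
        errs = self._cohort(0.0)
        assert (errs <= 1).mean() >= 0.90

    def test_default_noise_within_two_frames(self):
        errs = self._cohort(0.04)
        assert (errs <= 2).mean() >= 0.90


def make_track(frames, xy=(1000.0, 1000.0)):
    dets = [PitDetection(frame=f, x_nm=xy[0], y_nm=xy[1], depth_nm=30.0,
                         diameter_nm=200.0, score=30.0) for f in frames]
    return PitTrack(track_id=0, detections=dets)


class TestEventTimes:
    def test_simple_track_arithmetic(self):
        track = make_track(range(3, 11))
        t_inv, t_clo = detect_event_times(track, n_frames=40, dt_s=10.0)
        assert t_inv == 30.0
        assert t_clo == 110.0

    def test_open_at_last_frame_censored(self):
        track = make_track(range(30, 40))
        _, t_clo = detect_event_times(track, n_frames=40, dt_s=10.0)
        assert t_clo is None

    def test_reopen_track_uses_final_closure(self):
        track = make_track(list(range(3, 8)) + list(range(11, 15)))
        track.gaps = [(8, 11)]
        _, t_clo = detect_event_times(track, n_frames=40, dt_s=10.0)
        assert t_clo == 150.0


class TestRelativeTiming:
    def test_background_trace_marked_absent(self):
        tr = trace_of(np.zeros(20), sigma=1.0)
        with pytest.raises(ChannelAbsentError):
            relative_timing(tr, 0.0, 100.0)

    def test_offsets_reported_against_both_anchors(self):
        vals = np.concatenate([np.zeros(5), trapezoid(), np.zeros(5)])
        tr = trace_of(vals, sigma=0.01)
        et = relative_timing(tr, t0_invagination_s=80.0, t0_closure_s=150.0)
        assert et.appearance_s <= et.peak_s <= et.disappearance_s
        assert et.vs_invagination["appearance"] == \
            pytest.approx(et.appearance_s - 80.0)
        assert et.vs_closure["disappearance"] == \
            pytest.approx(et.disappearance_s - 150.0)
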