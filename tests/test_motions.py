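"""Closing-motion detection and classification."""

import numpy as np
import pytest

from hsafm_cme.detection import detect_movie
from hsafm_cme.generate import generate_dataset
from hsafm_cme.motions import (NotClassifiableError, classify_closing,
                               detect_swelling, motion_summary)
from hsafm_cme.pipeline import measure_track_diameters, run_analyze
from hsafm_cme.tracking import link_tracks

from conftest import single_event_config

PX = 18.75


def event_track_and_diams(cfg):
    bundle = generate_dataset(cfg)
    tracks = link_tracks(detect_movie(bundle.height.frames, PX,
                                      bundle.height.artifact_log))
    track = max(tracks, key=lambda t: len(t.detections))
    df = measure_track_diameters(bundle.height, track, cfg.tip_radius_nm)
    dmap = {}
    for _, r in df.iterrows():
        d = r["diameter_raw_nm"]
        dmap[int(r["frame"])] = float(d) if np.isfinite(d) \
            else float(r["diameter_detection_nm"])
    return bundle, track, dmap


class TestSwellingDetection:
    def test_capping_event_measured_geometry(self):
        diams, heights = [], []
        for seed in range(12):
            cfg = single_event_config("capping", seed)
            bundle, track, _ = event_track_and_diams(cfg)
            rec = detect_swelling(bundle.height.frames, track, PX)
            if rec is None:
                continue
            truth = bundle.truth.events[0].swelling
            diams.append(rec.diameter_nm - truth.diameter_nm)
            heights.append(rec.height_nm - truth.height_nm)
        assert len(diams) >= 8
        assert abs(np.mean(diams)) < 2 * PX
        assert abs(np.mean(heights)) < 5.0

    def test_plain_closure_has_no_swelling(self):
        cfg = single_event_config("plain", 1)
        bundle, track, _ = event_track_and_diams(cfg)
        assert detect_swelling(bundle.height.frames, track, PX) is None


class TestClassification:
    @pytest.mark.parametrize("motion", ["capping", "two_step", "reopen",
                                        "plain"])
    def test_single_motion_events_recovered(self, motion):
        hits = total = 0
        for seed in range(8):
            cfg = single_event_config(motion, 100 + seed)
            bundle, track, dmap = event_track_and_diams(cfg)
            if track.closure_frame(cfg.n_frames) is None:
                continue
            swelling = detect_swelling(bundle.height.frames, track, PX)
            ann = classify_closing(track, swelling, dmap, cfg.n_frames, 10.0)
            total += 1
            hits += motion in ann.labels
        assert total >= 6
        assert hits / total >= 0.75

    def test_reopen_displacement_and_gap_reported(self):
        for seed in range(6):
            cfg = single_event_config("reopen", 40 + seed)
            bundle, track, dmap = event_track_and_diams(cfg)
            ev = bundle.truth.events[0]
            swelling = detect_swelling(bundle.height.frames, track, PX)
            ann = classify_closing(track, swelling, dmap, cfg.n_frames, 10.0)
            if "reopen" not in ann.labels:
                continue
            assert ann.reopen_gap_s == pytest.approx(
                (ev.reopen_gap_frames[1] - ev.reopen_gap_frames[0]) * 10.0)
            assert ann.reopen_displacement_nm == pytest.approx(
                ev.reopen_displacement_nm, abs=60.0)
            return
        pytest.fail("no re-opening event classified")

    def test_retention_fraction_recovered(self):
        """Clathrin retained during the closed gap ~ its scripted fraction."""
        cfg = single_event_config("reopen", 11, channels=("clathrin",))
        bundle = generate_dataset(cfg)
        result = run_analyze(bundle)
        ev = bundle.truth.events[0]
        for ann in result.annotations:
            if "reopen" in ann.labels and ann.reopen_retention is not None:
                assert ann.reopen_retention == pytest.approx(
                    ev.reopen_retention, abs=0.15)
                return
        pytest.fail("no retention measured")

    def test_unclosed_track_not_classifiable(self):
        from hsafm_cme.tracking import PitTrack
        from hsafm_cme.detection import PitDetection

        dets = [PitDetection(frame=f, x_nm=500.0, y_nm=500.0, depth_nm=30.0,
                             diameter_nm=200.0, score=30.0) for f in range(36, 40)]
        track = PitTrack(track_id=0, detections=dets)
        with pytest.raises(NotClassifiableError):
            classify_closing(track, None, {}, n_frames=40, dt_s=10.0)


class TestMotionSummary:
    def _annotation(self, eid, labels):
        from hsafm_cme.motions import ClosingAnnotation

        return ClosingAnnotation(event_id=eid, labels=frozenset(labels),
                                 closing_duration_s=30.0)

    def test_percentage_arithmetic(self):
        anns = [self._annotation(i, {"capping"}) for i in range(55)]
        anns += [self._annotation(55 + i, {"plain"}) for i in range(45)]
        summary = motion_summary(anns)
        assert summary.percentages["capping"] == pytest.approx(55.0)

    def test_crosstab_marginals_consistent(self):
        anns = [self._annotation(0, {"capping"}),
                self._annotation(1, {"reopen"}),
                self._annotation(2, {"capping"}),
                self._annotation(3, {"plain"})]
        summary = motion_summary(anns)
        assert summary.crosstab.to_numpy().sum() == 4
        assert summary.crosstab.loc["capping"].sum() == 2

    def test_order_invariance(self):
        anns = [self._annotation(i, {"capping"} if i % 3 else {"plain"})
                for i in range(30)]
        a = motion_summary(anns).percentages
        b = motion_summary(list(reversed(anns))).percentages
        assert a == b

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            motion_summary([])
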