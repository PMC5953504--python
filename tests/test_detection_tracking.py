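"""Pit detection, track linking, identity and lifetime statistics."""

import numpy as np
import pytest

from hsafm_cme.detection import PitDetection, detect_movie, detect_pits
from hsafm_cme.pipeline import bundle_transform, match_tracks_to_truth
from hsafm_cme.render import _add_radial
from hsafm_cme.tracking import (PitTrack, assign_identity, lifetime_and_rate,
                                link_tracks)

from conftest import in_field_config

PX = 18.75


class TestDetection:
    def test_flat_frame_empty(self):
        assert detect_pits(np.zeros((64, 64)), PX) == []

    def test_single_pit_centroid_within_one_pixel(self):
        grid = np.zeros((96, 96))
        _add_radial(grid, PX, (901.0, 905.0), 150.0, -30.0)
        dets = detect_pits(grid, PX)
        assert len(dets) == 1
        assert np.hypot(dets[0].x_nm - 901.0, dets[0].y_nm - 905.0) < PX
        assert dets[0].depth_nm == pytest.approx(30.0, abs=3.0)

    def test_two_pits_500nm_apart_resolved(self):
        grid = np.zeros((96, 96))
        _add_radial(grid, PX, (700.0, 900.0), 100.0, -30.0)
        _add_radial(grid, PX, (1200.0, 900.0), 100.0, -30.0)
        assert len(detect_pits(grid, PX)) == 2

    def test_artifact_rows_excluded(self):
        grid = np.zeros((96, 96))
        _add_radial(grid, PX, (901.0, 905.0), 150.0, -30.0)
        rows = list(range(40, 58))
        assert detect_pits(grid, PX, artifact_rows=rows) == []


def stationary_dets(frames, xy, jitter=0.0, rng=None):
    out = []
    for f in frames:
        x, y = xy
        if jitter and rng is not None:
            x, y = x + rng.normal(0, jitter), y + rng.normal(0, jitter)
        out.append(PitDetection(frame=f, x_nm=x, y_nm=y, depth_nm=30.0,
                                diameter_nm=200.0, score=30.0))
    return out


class TestLinking:
    def test_stationary_detections_single_gapless_track(self):
        by_frame = [[d] for d in stationary_dets(range(10), (500.0, 500.0))]
        tracks = link_tracks(by_frame)
        assert len(tracks) == 1
        assert tracks[0].gaps == []
        assert list(tracks[0].frames) == list(range(10))

    def test_large_jump_splits_tracks(self):
        by_frame = [[d] for d in stationary_dets(range(5), (500.0, 500.0))]
        by_frame += [[d] for d in stationary_dets(range(5, 10), (2500.0, 2500.0))]
        tracks = link_tracks(by_frame)
        assert len(tracks) == 2

    def test_gap_closing_bridges_reopen(self):
        frames_a = stationary_dets(range(0, 6), (500.0, 500.0))
        frames_b = stationary_dets(range(9, 14), (550.0, 500.0))
        by_frame = [[] for _ in range(14)]
        for d in frames_a + frames_b:
            by_frame[d.frame].append(d)
        tracks = link_tracks(by_frame)
        assert len(tracks) == 1
        assert tracks[0].gaps == [(6, 9)]

    def test_no_detection_shared_between_tracks(self, small_bundle):
        dets = detect_movie(small_bundle.height.frames, PX,
                            small_bundle.height.artifact_log)
        tracks = link_tracks(dets)
        seen = set()
        for tr in tracks:
            for d in tr.detections:
                key = id(d)
                assert key not in seen
                seen.add(key)

    def test_synthetic_reopen_event_tracked_with_gap(self):
        from hsafm_cme.generate import generate_dataset
        from conftest import single_event_config

        cfg = single_event_config("reopen", 7)
        bundle = generate_dataset(cfg)
        ev = bundle.truth.events[0]
        tracks = link_tracks(detect_movie(bundle.height.frames, PX,
                                          bundle.height.artifact_log))
        track = max(tracks, key=lambda t: len(t.detections))
        assert ev.reopen_gap_frames in track.gaps


def test_detection_recall_precision_against_truth():
    """Aggregate tracking precision/recall over several movies >= 0.9 at
    the default SNR (single movies can lose one event to a pit-pit
    collision and identity switch)."""
    from hsafm_cme.generate import generate_dataset

    n_matched = n_tracks = n_truth = 0
    for seed in (0, 1, 2):
        bundle = generate_dataset(in_field_config(channels=(), seed=seed))
        tracks = link_tracks(detect_movie(bundle.height.frames, PX,
                                          bundle.height.artifact_log))
        matched = match_tracks_to_truth(tracks, bundle.truth)
        n_matched += len(matched)
        n_tracks += len(tracks)
        n_truth += len(bundle.truth.events)
    assert n_matched / n_tracks >= 0.9
    assert n_matched / n_truth >= 0.9


def test_identity_by_marker_colocalization(small_bundle,
                                           analyzed_small_bundle):
    """All events carry clathrin: every matched track reads as a CCP."""
    transform = bundle_transform(small_bundle.config)
    matched = match_tracks_to_truth(analyzed_small_bundle.tracks,
                                    small_bundle.truth)
    for tr in analyzed_small_bundle.tracks:
        if tr.track_id not in matched:
            continue
        assert assign_identity(tr, small_bundle.fluor, transform) == "CCP"


def test_markerless_size_prior():
    small = PitTrack(track_id=0, detections=stationary_dets(
        range(5), (500.0, 500.0)))
    for d in small.detections:
        d.diameter_nm = 100.0
    assert assign_identity(small, {}, None) == "caveola-like"
    for d in small.detections:
        d.diameter_nm = 250.0
    assert assign_identity(small, {}, None) == "CCP-like"


class TestLifetimeAndRate:
    def test_lifetime_arithmetic(self):
        track = PitTrack(track_id=0, detections=stationary_dets(
            range(5, 14), (500.0, 500.0)))
        table, _ = lifetime_and_rate([track], 27.0, 900.0, 90, 10.0)
        assert table.loc[0, "lifetime_s"] == 90.0

    def test_formation_frequency_arithmetic(self):
        tracks = [PitTrack(track_id=i, detections=stationary_dets(
            [3 + i, 4 + i], (500.0 + 300 * i, 500.0))) for i in range(12)]
        _, rate = lifetime_and_rate(tracks, 27.0, 900.0, 90, 10.0)
        assert rate == pytest.approx(12 / (27.0 * 15.0))

    def test_censored_tracks_excluded(self):
        edge = PitTrack(track_id=0, detections=stationary_dets(
            range(85, 90), (500.0, 500.0)))
        table, _ = lifetime_and_rate([edge], 27.0, 900.0, 90, 10.0)
        assert bool(table.loc[0, "censored"])
        assert np.isnan(table.loc[0, "lifetime_s"])

    def test_lifetimes_never_exceed_movie_duration(self, small_bundle,
                                                   analyzed_small_bundle):
        table = analyzed_small_bundle.lifetimes
        duration = small_bundle.config.n_frames * 10.0
        finite = table["lifetime_s"].dropna()
        assert (finite <= duration).all()

    def test_zero_duration_movie_rejected(self):
        with pytest.raises(ValueError):
            lifetime_and_rate([], 27.0, 0.0, 0, 10.0)
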