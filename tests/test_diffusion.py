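"""Drift estimation, MSD computation and diffusion fitting."""

import numpy as np
import pytest

from hsafm_cme.config import D_CAVEOLA_CM2_S, D_CCP_CM2_S
from hsafm_cme.detection import PitDetection
from hsafm_cme.diffusion import (InsufficientDataError, MSDCurve, compute_msd,
                                 ensemble_msd, estimate_drift, fit_diffusion,
                                 net_displacement_nm)
from hsafm_cme.studies import (diffusion_recovery_study,
                               tracks_from_trajectories)
from hsafm_cme.tracking import PitTrack
from hsafm_cme.trajectory import sample_trajectory


def track_from(positions, frames=None):
    frames = range(len(positions)) if frames is None else frames
    dets = [PitDetection(frame=f, x_nm=p[0], y_nm=p[1], depth_nm=30.0,
                         diameter_nm=200.0, score=30.0)
            for f, p in zip(frames, positions)]
    return PitTrack(track_id=0, detections=dets)


class TestDriftEstimate:
    def test_common_translation_recovered(self):
        base = np.array([[0, 0], [0, 0], [0, 0]], dtype=float)
        drift = np.array([[0, 0], [50, 0], [100, 0]], dtype=float)
        tracks = [track_from(base + drift + off)
                  for off in ([0, 0], [500, 100], [900, 800])]
        est = estimate_drift(tracks, 3)
        np.testing.assert_allclose(est.cum_drift_nm[-1], [100.0, 0.0])

    def test_stationary_pit_zero_drift(self):
        est = estimate_drift([track_from(np.zeros((5, 2)))], 5)
        np.testing.assert_allclose(est.cum_drift_nm, 0.0)

    def test_first_last_mode_matches_net_displacement(self):
        pos = np.cumsum(np.ones((10, 2)) * 7.0, axis=0)
        est = estimate_drift([track_from(pos)], 10, method="first-last")
        np.testing.assert_allclose(est.cum_drift_nm[-1], pos[-1] - pos[0])

    def test_no_usable_track_raises(self):
        with pytest.raises(InsufficientDataError):
            estimate_drift([track_from(np.zeros((1, 2)))], 5)

    def test_brownian_ensemble_net_displacement_near_zero(self):
        rng = np.random.default_rng(3)
        pos = [sample_trajectory(D_CCP_CM2_S, (0, 0), 40, 10.0, rng)
               for _ in range(2000)]
        net = net_displacement_nm(tracks_from_trajectories(pos))
        se = np.sqrt(2 * D_CCP_CM2_S * 1e14 * 10.0 * 39 / 2000)
        assert np.hypot(*net) < 3 * se * np.sqrt(2)


class TestMSD:
    def test_two_point_track(self):
        msd = compute_msd(track_from([[0, 0], [30, 40]]), dt_s=10.0)
        assert msd.lag_s[0] == 10.0
        assert msd.msd_nm2[0] == pytest.approx(2500.0)

    def test_pure_drift_cancels_after_correction(self):
        pos = np.outer(np.arange(20), [15.0, -5.0])
        track = track_from(pos)
        drift = estimate_drift([track], 20)
        msd = compute_msd(track, drift, dt_s=10.0)
        assert np.all(msd.msd_nm2 < 1e-12)

    def test_uncorrected_linear_motion_is_quadratic(self):
        v = 12.0
        pos = np.outer(np.arange(30), [v, 0.0])
        msd = compute_msd(track_from(pos), dt_s=1.0)
        np.testing.assert_allclose(msd.msd_nm2, (v * msd.lag_s) ** 2)

    def test_gaps_excluded_from_pair_counts(self):
        frames = [0, 1, 2, 6, 7]
        msd = compute_msd(track_from(np.zeros((5, 2)), frames), dt_s=10.0)
        counts = dict(zip(msd.lag_s, msd.counts))
        assert counts[10.0] == 3            # (0,1), (1,2), (6,7)

    def test_single_detection_raises(self):
        with pytest.raises(InsufficientDataError):
            compute_msd(track_from([[0, 0]]))


class TestFitDiffusion:
    def test_exact_linear_msd_recovered(self):
        d_nm2 = 1000.0
        lags = np.array([10.0, 20.0, 30.0, 40.0])
        msd = MSDCurve(lag_s=lags, msd_nm2=4 * d_nm2 * lags,
                       counts=np.full(4, 100))
        est = fit_diffusion(msd)
        assert est.d_cm2_s == pytest.approx(d_nm2 / 1e14)
        assert not est.negative_slope

    def test_negative_slope_flagged_and_clipped(self):
        lags = np.array([10.0, 20.0, 30.0, 40.0])
        msd = MSDCurve(lag_s=lags, msd_nm2=-5.0 * lags, counts=np.full(4, 100))
        est = fit_diffusion(msd)
        assert est.d_cm2_s == 0.0
        assert est.negative_slope

    def test_insufficient_counts_raise(self):
        msd = MSDCurve(lag_s=np.array([10.0]), msd_nm2=np.array([100.0]),
                       counts=np.array([3]))
        with pytest.raises(InsufficientDataError):
            fit_diffusion(msd)


class TestRecovery:
    def test_ccp_and_caveola_d_recovered_within_15_percent(self):
        for identity, d_true in (("CCP", D_CCP_CM2_S),
                                 ("caveola", D_CAVEOLA_CM2_S)):
            est = diffusion_recovery_study(2, identity=identity)
            assert est.d_cm2_s == pytest.approx(d_true, rel=0.15)

    def test_class_ordering_preserved(self):
        for seed in range(5):
            ccp = diffusion_recovery_study(seed, identity="CCP",
                                           n_tracks=60)
            cav = diffusion_recovery_study(seed, identity="caveola",
                                           n_tracks=60)
            assert cav.d_cm2_s < ccp.d_cm2_s

    def test_drift_invariance_within_2_percent(self):
        a = diffusion_recovery_study(4, drift_nm_per_frame=(0.0, 0.0))
        b = diffusion_recovery_study(4, drift_nm_per_frame=(20.0, 0.0))
        assert abs(a.d_cm2_s - b.d_cm2_s) / a.d_cm2_s < 0.02

    def test_unbiased_over_replicates(self):
        """Ensemble D unbiased within 3 SE over 20 seed replicates."""
        ests = np.array([diffusion_recovery_study(s, n_tracks=50).d_cm2_s
                         for s in range(20)])
        se = ests.std(ddof=1) / np.sqrt(len(ests))
        assert abs(ests.mean() - D_CCP_CM2_S) < 3 * se
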