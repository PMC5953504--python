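"""Height-frame rendering, tip convolution and scan artifacts."""

import dataclasses

import numpy as np
import pytest

from hsafm_cme.config import ArtifactRates, NoiseParams
from hsafm_cme.events import sample_events
from hsafm_cme.morphometry import measure_diameter, section_profile
from hsafm_cme.render import (_add_radial, apply_tip_convolution,
                              apply_tip_skip, background_field,
                              inject_scan_artifacts, render_height_frame,
                              tip_structure)

from conftest import in_field_config, single_event_config

PX = 18.75


def brute_force_dilation(grid: np.ndarray, tip_radius: float,
                         px: float) -> np.ndarray:
    """Independent max-over-footprint imaging model."""
    s = tip_structure(tip_radius, px)
    r = s.shape[0] // 2
    rows, cols = grid.shape
    out = np.full_like(grid, -np.inf)
    for i in range(rows):
        for j in range(cols):
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    if s[r + di, r + dj] < -1e8:
                        continue
                    ii = min(max(i + di, 0), rows - 1)
                    jj = min(max(j + dj, 0), cols - 1)
                    out[i, j] = max(out[i, j], grid[ii, jj] + s[r + di, r + dj])
    return out


def test_empty_noiseless_frame_is_flat():
    cfg = single_event_config("plain", 0, n_events=0,
                              noise=NoiseParams(roughness_nm=0.0))
    frame = render_height_frame([], 0, cfg)
    assert np.all(frame == 0.0)


@pytest.mark.parametrize("aperture", [150.0, 300.0, 400.0])
def test_rendered_pit_diameter_matches_aperture(aperture):
    """Baseline-crossing diameter of a noiseless rendered pit equals its
    scripted aperture within one pixel (independent 1-D profile check)."""
    grid = np.zeros((128, 128))
    center = (1204.0, 1198.0)
    _add_radial(grid, PX, center, aperture / 2.0, -30.0)
    prof = section_profile(grid, center, 0.0, 1.6 * aperture, PX)
    assert measure_diameter(prof) == pytest.approx(aperture, abs=PX)


def test_capping_swelling_peak_height():
    """At the swelling peak the frame maximum sits ~height above baseline."""
    cfg = single_event_config("capping", 3, noise=NoiseParams(roughness_nm=0.0))
    events = sample_events(cfg, np.random.default_rng(cfg.seed))
    ev = events[0]
    assert ev.swelling is not None
    frame = render_height_frame(events, ev.swelling.peak_frame, cfg)
    peak_above_baseline = frame.max() - np.median(frame)
    assert peak_above_baseline == pytest.approx(ev.swelling.height_nm, rel=0.05)


def test_background_field_statistics(rng):
    field = background_field((200, 200), 2.0, 100.0, PX, rng)
    assert field.std() == pytest.approx(2.0, rel=0.05)
    assert abs(field.mean()) < 0.2


class TestTipConvolution:
    def test_zero_radius_is_identity(self, rng):
        g = rng.normal(0, 5, (20, 20))
        np.testing.assert_array_equal(apply_tip_convolution(g, 0.0, PX), g)

    def test_flat_plane_unchanged(self):
        g = np.full((20, 20), 3.5)
        np.testing.assert_allclose(apply_tip_convolution(g, 50.0, PX), g)

    def test_matches_brute_force_on_spike(self):
        g = np.zeros((15, 15))
        g[7, 7] = 50.0
        np.testing.assert_allclose(apply_tip_convolution(g, 45.0, PX),
                                   brute_force_dilation(g, 45.0, PX))

    def test_output_dominates_input(self, rng):
        g = rng.normal(0, 10, (25, 25))
        assert np.all(apply_tip_convolution(g, 40.0, PX) >= g - 1e-9)

    def test_oversized_tip_rejected(self):
        with pytest.raises(ValueError):
            apply_tip_convolution(np.zeros((10, 10)), 1e5, PX)

    def test_apparent_aperture_non_increasing_in_tip_radius(self):
        """Dilation shrinks depressions: measured aperture never grows
        with tip radius."""
        grid = np.zeros((128, 128))
        center = (1200.0, 1200.0)
        _add_radial(grid, PX, center, 150.0, -30.0)
        diams = []
        for radius in (0.0, 20.0, 40.0, 60.0):
            imaged = apply_tip_convolution(grid, radius, PX)
            prof = section_profile(imaged, center, 0.0, 500.0, PX)
            diams.append(measure_diameter(prof))
        assert all(b <= a + 1e-9 for a, b in zip(diams[:-1], diams[1:]))


class TestScanArtifacts:
    def test_zero_rates_identity(self, rng):
        g = rng.normal(0, 5, (40, 40))
        out, log = inject_scan_artifacts(g, ArtifactRates(0.0, 0.0), rng)
        np.testing.assert_array_equal(out, g)
        assert log == []

    def test_forced_skip_touches_only_target_rows(self, rng):
        g = rng.normal(0, 5, (40, 40))
        out = apply_tip_skip(g, row=17, width=2, offset_nm=8.0)
        changed = np.flatnonzero(np.any(out != g, axis=1))
        assert list(changed) == [17, 18]
        np.testing.assert_allclose(out[17], g[16] + 8.0)

    def test_skip_width_approximates_37_nm(self, rng):
        """1-2 consecutive lines at 18.75 nm/px: worst case 2 x 18.75 = 37.5."""
        widths = []
        arr = ArtifactRates(tip_skip_per_frame=1.0, amplitude_step_per_frame=0.0)
        g = np.zeros((40, 40))
        for _ in range(200):
            _, log = inject_scan_artifacts(g, arr, rng)
            widths.append(len(log[0]["rows"]) * PX)
        assert set(widths) == {18.75, 37.5}

    def test_injections_are_logged(self, rng):
        arr = ArtifactRates(tip_skip_per_frame=1.0, amplitude_step_per_frame=1.0)
        out, log = inject_scan_artifacts(np.random.default_rng(1).normal(0, 5, (30, 30)),
                                         arr, rng, frame=4)
        kinds = {entry["type"] for entry in log}
        assert kinds == {"tip_skip", "amplitude_step"}
        assert all(entry["frame"] == 4 for entry in log)
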