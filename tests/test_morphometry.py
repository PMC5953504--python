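"""Section-profile morphometry and the morphological area pipeline."""

import numpy as np
import pytest

from hsafm_cme.morphometry import (NoPeakError, NoPitError, SectionProfile,
                                   measure_area, measure_bump_width,
                                   measure_diameter, measure_height,
                                   pit_area_response, section_profile,
                                   tip_correct)
from hsafm_cme.render import _add_radial

PX = 18.75


def pit_grid(aperture, center=(1200.0, 1200.0), depth=30.0, shape=(128, 128)):
    g = np.zeros(shape)
    _add_radial(g, PX, center, aperture / 2.0, -depth)
    return g


class TestSectionProfile:
    def test_flat_grid_constant(self):
        prof = section_profile(np.full((64, 64), 2.0), (600.0, 600.0),
                               0.0, 400.0, PX)
        assert np.all(prof.heights_nm == 2.0)

    def test_profile_through_pit_symmetric_minimum(self):
        prof = section_profile(pit_grid(300.0), (1200.0, 1200.0), 0.0, 500.0, PX)
        i_min = int(np.argmin(prof.heights_nm))
        assert abs(prof.positions_nm[i_min]) <= PX
        half = len(prof) // 2
        np.testing.assert_allclose(prof.heights_nm[:half],
                                   prof.heights_nm[:-half - 1:-1], atol=1.0)

    def test_angles_agree_on_isotropic_pit(self):
        g = pit_grid(300.0)
        d = [measure_diameter(section_profile(g, (1200.0, 1200.0), ang,
                                              500.0, PX))
             for ang in (0.0, np.pi / 2)]
        assert abs(d[0] - d[1]) <= PX

    def test_center_outside_grid_raises(self):
        with pytest.raises(ValueError):
            section_profile(np.zeros((32, 32)), (1e5, 1e5), 0.0, 100.0, PX)


class TestDiameter:
    @pytest.mark.parametrize("aperture", [120.0, 150.0, 200.0, 300.0, 400.0])
    @pytest.mark.parametrize("angle", [0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4])
    def test_unbiased_within_one_pixel_noiseless(self, aperture, angle):
        errs = []
        for off in np.linspace(0.0, PX, 5):
            center = (1200.0 + off, 1200.0 + 0.37 * off)
            prof = section_profile(pit_grid(aperture, center), center, angle,
                                   1.6 * aperture, PX)
            errs.append(measure_diameter(prof) - aperture)
        assert abs(np.mean(errs)) < PX
        assert np.abs(errs).max() < 1.5 * PX

    def test_flat_profile_raises(self):
        prof = SectionProfile(positions_nm=np.arange(20) * PX,
                              heights_nm=np.zeros(20), angle_rad=0.0,
                              spacing_nm=PX)
        with pytest.raises(NoPitError):
            measure_diameter(prof)


class TestHeight:
    def _bump_profile(self, height, tilt=0.0, width=378.0):
        pos = (np.arange(-30, 31)) * PX
        z = np.where(np.abs(pos) < width / 2,
                     height * np.cos(np.pi * pos / width), 0.0)
        z = z + tilt * pos / pos.max() * 5.0
        return SectionProfile(positions_nm=pos, heights_nm=z, angle_rad=0.0,
                              spacing_nm=PX)

    def test_symmetric_bump_height_recovered(self):
        assert measure_height(self._bump_profile(38.0)) == pytest.approx(38.0,
                                                                         abs=1.0)

    def test_flat_profile_raises(self):
        prof = SectionProfile(positions_nm=np.arange(20) * PX,
                              heights_nm=np.zeros(20), angle_rad=0.0,
                              spacing_nm=PX)
        with pytest.raises(NoPeakError):
            measure_height(prof)

    def test_tilted_baseline_within_2nm(self):
        assert measure_height(self._bump_profile(38.0, tilt=1.0)) == \
            pytest.approx(38.0, abs=2.0)

    def test_bump_width_matches_truth(self):
        w = measure_bump_width(self._bump_profile(38.0, width=378.0))
        assert w == pytest.approx(378.0, abs=1.5 * PX)


class TestTipCorrect:
    def test_reference_values(self):
        assert tip_correct(150.0, 10.0) == 130.0
        assert tip_correct(400.0, 10.0) == 380.0

    def test_zero_radius_identity(self):
        assert tip_correct(237.0, 0.0) == 237.0

    def test_domain_error(self):
        with pytest.raises(ValueError):
            tip_correct(15.0, 10.0)


# ---------------------------------------------------------------------------
# morphological area pipeline vs a brute-force oracle
# ---------------------------------------------------------------------------

def _disk_offsets(radius):
    out = []
    for dy in range(-radius, radius + 1):
        for dx in range(-radius, radius + 1):
            if dx * dx + dy * dy <= radius * radius:
                out.append((dy, dx))
    return out


def _erode(img, offs):
    rows, cols = img.shape
    out = np.empty_like(img)
    for i in range(rows):
        for j in range(cols):
            vals = [img[i + dy, j + dx] for dy, dx in offs
                    if 0 <= i + dy < rows and 0 <= j + dx < cols]
            out[i, j] = min(vals)
    return out


def _dilate(img, offs):
    rows, cols = img.shape
    out = np.empty_like(img)
    for i in range(rows):
        for j in range(cols):
            vals = [img[i + dy, j + dx] for dy, dx in offs
                    if 0 <= i + dy < rows and 0 <= j + dx < cols]
            out[i, j] = max(vals)
    return out


def _median3(img):
    padded = np.pad(img, 1, mode="reflect")
    rows, cols = img.shape
    out = np.empty_like(img)
    for i in range(rows):
        for j in range(cols):
            out[i, j] = np.median(padded[i:i + 3, j:j + 3])
    return out


def oracle_area_response(grid, tophat_diam=20, oc_diam=6):
    med = _median3(grid.astype(float))
    big, small = _disk_offsets(tophat_diam // 2), _disk_offsets(oc_diam // 2)
    response = _erode(_dilate(med, big), big) - med          # black top-hat
    response = _dilate(_erode(response, small), small)       # opening
    response = _erode(_dilate(response, small), small)       # closing
    return response


def flat_disk(shape, center, radius_px, depth=30.0):
    g = np.zeros(shape)
    ys, xs = np.mgrid[0:shape[0], 0:shape[1]]
    g[(xs - center[0]) ** 2 + (ys - center[1]) ** 2 <= radius_px ** 2] = -depth
    return g


class TestAreaPipeline:
    def test_matches_brute_force_oracle(self, rng):
        g = flat_disk((44, 44), (21.5, 22.2), 5.0)
        g += rng.normal(0, 1.0, g.shape)
        fast = pit_area_response(g)
        slow = oracle_area_response(g)
        interior = (slice(11, 33), slice(11, 33))
        mask_fast = fast[interior] > 0.5 * fast[interior].max()
        mask_slow = slow[interior] > 0.5 * slow[interior].max()
        np.testing.assert_array_equal(mask_fast, mask_slow)

    def test_flat_roi_zero(self):
        assert measure_area(np.zeros((50, 50)), (slice(5, 45), slice(5, 45)),
                            PX) == 0.0

    def test_disk_area_within_15_percent(self):
        g = flat_disk((60, 60), (30.5, 30.2), 5.0)
        area = measure_area(g, (slice(10, 50), slice(10, 50)), PX)
        assert area == pytest.approx(np.pi * (5 * PX) ** 2, rel=0.15)

    def test_structure_wider_than_tophat_removed(self):
        g = flat_disk((80, 80), (40.0, 40.0), 15.0)
        assert measure_area(g, (slice(5, 75), slice(5, 75)), PX) == 0.0

    def test_empty_roi_raises(self):
        with pytest.raises(ValueError):
            measure_area(np.zeros((20, 20)), (slice(5, 5), slice(0, 0)), PX)

    def test_area_tracks_diameter(self):
        """Both operators report the same structure: the area matches the
        true footprint within 15% and the section diameter matches the
        true width within 1.5 px (their mutual consistency is limited by
        the one-pixel edge accuracy on a sub-500-nm structure)."""
        r_px = 7.0
        g = flat_disk((80, 80), (40.5, 40.2), r_px)
        area = measure_area(g, (slice(10, 70), slice(10, 70)), PX)
        prof = section_profile(g, (40.5 * PX + PX / 2, 40.2 * PX + PX / 2),
                               0.0, 600.0, PX)
        d = measure_diameter(prof)
        d_true = (2 * r_px + 1) * PX
        assert area == pytest.approx(np.pi * (r_px * PX) ** 2, rel=0.15)
        assert d == pytest.approx(d_true, abs=1.5 * PX)
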