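"""Section-profile morphometry of AFM height images.

The measurement operators mirror the manual cross-section analysis used
on AFM scans of endocytic pits: a line profile through the structure,
the aperture diameter as the horizontal distance between the two edge
points where the profile returns to the local baseline, the swelling
height as peak minus the mean of the two basal levels, a subtraction of
the tip curvature (2 x tip radius) from measured diameters, and a
morphological-filter pipeline (median -> black top-hat -> open-close ->
threshold) for the pit area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import morphology


class NoPitError(ValueError):
    """Profile contains no qualifying depression."""


class NoPeakError(ValueError):
    """Profile contains no qualifying peak."""


class ProfileTruncationError(ValueError):
    """The requested section line leaves the grid before an edge is found."""


@dataclass
class SectionProfile:
    """Heights sampled along a line through a centre point."""

    positions_nm: np.ndarray     # signed distance from the centre, increasing
    heights_nm: np.ndarray
    angle_rad: float
    spacing_nm: float
    truncated: bool = False

    def __post_init__(self) -> None:
        self.positions_nm = np.asarray(self.positions_nm, dtype=float)
        self.heights_nm = np.asarray(self.heights_nm, dtype=float)
        if self.positions_nm.shape != self.heights_nm.shape:
            raise ValueError("positions and heights must have equal length")
        if np.any(np.diff(self.positions_nm) <= 0):
            raise ValueError("positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.positions_nm)


def section_profile(grid: np.ndarray, center_xy_nm: tuple[float, float],
                    angle_rad: float, half_length_nm: float,
                    pixel_size_nm: float) -> SectionProfile:
    """Bilinear line profile at one-pixel spacing through a centre point."""
    rows, cols = grid.shape
    cx, cy = center_xy_nm
    if not (0 <= cx <= cols * pixel_size_nm and 0 <= cy <= rows * pixel_size_nm):
        raise ValueError("section centre lies outside the grid")
    n_half = int(np.floor(half_length_nm / pixel_size_nm))
    s = np.arange(-n_half, n_half + 1) * pixel_size_nm
    xs = cx + s * np.cos(angle_rad)
    ys = cy + s * np.sin(angle_rad)
    # pixel-centre coordinates
    col_f = xs / pixel_size_nm - 0.5
    row_f = ys / pixel_size_nm - 0.5
    inside = ((col_f >= 0) & (col_f <= cols - 1)
              & (row_f >= 0) & (row_f <= rows - 1))
    truncated = not bool(inside.all())
    if truncated:
        keep = np.flatnonzero(inside)
        if keep.size < 3:
            raise ProfileTruncationError("section line lies almost entirely "
                                         "outside the grid")
        sl = slice(keep[0], keep[-1] + 1)
        s, col_f, row_f = s[sl], col_f[sl], row_f[sl]
    heights = ndimage.map_coordinates(grid.astype(float),
                                      np.vstack([row_f, col_f]), order=1)
    return SectionProfile(positions_nm=s, heights_nm=heights,
                          angle_rad=angle_rad, spacing_nm=pixel_size_nm,
                          truncated=truncated)


def _flank_baselines(profile: SectionProfile,
                     flank_fraction: float = 0.25) -> tuple[float, float]:
    n = len(profile)
    k = max(2, int(round(flank_fraction * n)))
    return (float(np.median(profile.heights_nm[:k])),
            float(np.median(profile.heights_nm[-k:])))


def _flank_sigma(profile: SectionProfile, flank_fraction: float = 0.25) -> float:
    n = len(profile)
    k = max(2, int(round(flank_fraction * n)))
    flanks = np.concatenate([profile.heights_nm[:k], profile.heights_nm[-k:]])
    return 1.4826 * float(np.median(np.abs(flanks - np.median(flanks))))


def _edge_position(pos: np.ndarray, z: np.ndarray, start: int, step: int,
                   threshold: float, baseline: float,
                   spacing: float) -> float:
    """Walk outward from ``start``, interpolate the threshold crossing and
    extrapolate along the local wall slope to the baseline itself.

    The threshold sits a noise-robust depth below the baseline (see
    :func:`measure_diameter`), so the crossing is found on the steep pit
    wall; the short extrapolation to the baseline removes the systematic
    inward bias a deep threshold would otherwise introduce.
    """
    i = start
    while 0 <= i < len(z):
        if z[i] >= threshold:
            if i == start:
                return float(pos[i])
            # project from the last below-threshold sample to the baseline
            # along the steepest adjacent chord: a chord straddling the rim
            # is diluted by the flat region outside, so the wall-side chord
            # is preferred when steeper
            j = i - step
            slope = abs(z[i] - z[j]) / abs(pos[i] - pos[j])
            k = j - step
            if 0 <= k < len(z):
                wall = abs(z[j] - z[k]) / abs(pos[j] - pos[k])
                slope = max(slope, wall)
            if slope <= 0:
                return float(pos[i])
            reach = min((baseline - z[j]) / slope, 2.5 * spacing)
            return float(pos[j] + step * reach)
        i += step
    raise ProfileTruncationError("profile edge not reached within the section")


def measure_diameter(profile: SectionProfile, depth_min_nm: float = 10.0,
                     edge_tolerance_nm: float = 1.0) -> float:
    """Aperture diameter: distance between the two baseline-edge points.

    The baseline is the mean of the two flank medians (outer 25% of the
    samples per side); the deepest point must lie at least
    ``depth_min_nm`` below it.  Each edge is the interpolated position,
    walking outward from the minimum, where the profile first returns to
    within ``edge_tolerance_nm`` of the baseline.
    """
    left, right = _flank_baselines(profile)
    baseline = 0.5 * (left + right)
    z = profile.heights_nm
    i_min = int(np.argmin(z))
    depth = baseline - z[i_min]
    if depth < depth_min_nm:
        raise NoPitError("no minimum deeper than depth_min below the baseline")
    # the edge threshold adapts to the flank noise and to the pit depth
    # (at least 15% of it) so background undulations cannot drag the edge
    # outward; the wall-slope projection in _edge_position removes the
    # inward bias a deep threshold would otherwise introduce
    tol = max(edge_tolerance_nm,
              min(max(3.0 * _flank_sigma(profile), 0.15 * depth), 0.5 * depth))
    threshold = baseline - tol
    e_left = _edge_position(profile.positions_nm, z, i_min, -1, threshold,
                            baseline, profile.spacing_nm)
    e_right = _edge_position(profile.positions_nm, z, i_min, +1, threshold,
                             baseline, profile.spacing_nm)
    return float(e_right - e_left)


def measure_height(profile: SectionProfile, min_height_nm: float = 2.0) -> float:
    """Peak height above the mean of the two basal levels.

    The peak is read from a lightly (3-sample) smoothed profile:
    taking the raw maximum of a noisy profile is biased upward by the
    largest noise excursion near the apex.
    """
    left, right = _flank_baselines(profile)
    basal = 0.5 * (left + right)
    z = profile.heights_nm
    smoothed = z.copy()
    if len(z) >= 3:
        smoothed[1:-1] = (z[:-2] + z[1:-1] + z[2:]) / 3.0
    peak = float(smoothed.max())
    if peak - max(left, right) < min_height_nm:
        raise NoPeakError("no peak above both flanks")
    return peak - basal


def measure_bump_width(profile: SectionProfile, min_height_nm: float = 10.0,
                       edge_tolerance_nm: float = 1.0) -> float:
    """Full width of a positive bump at the baseline (same edge rule as
    :func:`measure_diameter`, applied to the inverted profile)."""
    inverted = SectionProfile(positions_nm=profile.positions_nm,
                              heights_nm=-profile.heights_nm,
                              angle_rad=profile.angle_rad,
                              spacing_nm=profile.spacing_nm,
                              truncated=profile.truncated)
    return measure_diameter(inverted, depth_min_nm=min_height_nm,
                            edge_tolerance_nm=edge_tolerance_nm)


def tip_correct(diameter_raw_nm: float, tip_radius_nm: float) -> float:
    """Subtract the tip curvature (2 x tip radius) from a measured diameter."""
    if tip_radius_nm < 0:
        raise ValueError("tip radius must be >= 0")
    if diameter_raw_nm <= 2.0 * tip_radius_nm:
        raise ValueError("measured diameter not larger than the tip diameter")
    return diameter_raw_nm - 2.0 * tip_radius_nm


# ---------------------------------------------------------------------------
# morphological-filter area pipeline
# ---------------------------------------------------------------------------

def pit_area_response(grid: np.ndarray, tophat_diameter_px: int = 20,
                      openclose_diameter_px: int = 6) -> np.ndarray:
    """Filter response of the pit-area pipeline (before thresholding)."""
    med = ndimage.median_filter(grid.astype(float), size=3)
    se_top = morphology.disk(tophat_diameter_px // 2)
    response = morphology.black_tophat(med, se_top)
    se_oc = morphology.disk(openclose_diameter_px // 2)
    response = morphology.opening(response, se_oc)
    response = morphology.closing(response, se_oc)
    return response


def measure_area(grid: np.ndarray, roi: tuple[slice, slice],
                 pixel_size_nm: float, tophat_diameter_px: int = 20,
                 openclose_diameter_px: int = 6) -> float:
    """Pit area (nm^2) inside a region of interest.

    The image is median filtered, a black top-hat extracts depressions
    narrower than the large structuring element, an opening-closing pass
    removes speckle, and pixels above half the maximum response in the
    ROI are counted.
    """
    sub = grid[roi]
    if sub.size == 0:
        raise ValueError("empty region of interest")
    response = pit_area_response(grid, tophat_diameter_px, openclose_diameter_px)
    sub_resp = response[roi]
    peak = sub_resp.max()
    if peak <= 0:
        return 0.0
    mask = sub_resp > 0.5 * peak
    return float(mask.sum()) * pixel_size_nm ** 2
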