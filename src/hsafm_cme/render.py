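"""Rendering of AFM height frames and confocal fluorescence frames.

Coordinate convention: positions are in scan-local nanometres with the
origin at the top-left corner of the AFM scan area, x increasing along
columns and y increasing along rows.  Pixel (r, c) is centred at
``((c + 0.5) * px, (r + 0.5) * px)``.  The registration module maps this
frame onto the probe-centred common frame.

Open pits are rendered as radially symmetric depressions
``z(r) = -depth * cos(pi r / (2 a))`` for ``r < a`` (a = aperture
radius): the profile crosses the baseline exactly at ``r = a`` with a
finite rim slope, so the section-profile diameter of a noiseless pit
equals its scripted aperture.  Capping swellings are positive bumps of
the same radial family.  Tip convolution is a grayscale dilation with a
spherical-cap structure function, the standard imaging model for a
finite AFM tip.
"""

from __future__ import annotations

from typing import Any, Sequence

import numpy as np
from scipy import ndimage

from .config import SimulationConfig
from .events import EventSpec


# ---------------------------------------------------------------------------
# background
# ---------------------------------------------------------------------------

def background_field(shape: tuple[int, int], sigma_z_nm: float,
                     corr_length_nm: float, pixel_size_nm: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Smooth Gaussian random field emulating membrane roughness."""
    if sigma_z_nm <= 0:
        return np.zeros(shape)
    sigma_px = max(0.5, corr_length_nm / (2.0 * pixel_size_nm))
    field = rng.standard_normal(shape)
    field = ndimage.gaussian_filter(field, sigma_px, mode="reflect")
    sd = field.std()
    if sd > 0:
        field *= sigma_z_nm / sd
    return field


# ---------------------------------------------------------------------------
# height frames
# ---------------------------------------------------------------------------

def _add_radial(grid: np.ndarray, pixel_size_nm: float,
                center_xy_nm: tuple[float, float], radius_nm: float,
                amplitude_nm: float) -> None:
    """Add ``amplitude * cos(pi r / (2 radius))`` inside ``r < radius``."""
    if radius_nm <= 0 or amplitude_nm == 0:
        return
    rows, cols = grid.shape
    cx, cy = center_xy_nm
    c0 = max(0, int((cx - radius_nm) / pixel_size_nm) - 1)
    c1 = min(cols, int((cx + radius_nm) / pixel_size_nm) + 2)
    r0 = max(0, int((cy - radius_nm) / pixel_size_nm) - 1)
    r1 = min(rows, int((cy + radius_nm) / pixel_size_nm) + 2)
    if c0 >= c1 or r0 >= r1:
        return
    xs = (np.arange(c0, c1) + 0.5) * pixel_size_nm - cx
    ys = (np.arange(r0, r1) + 0.5) * pixel_size_nm - cy
    rr = np.hypot(xs[None, :], ys[:, None])
    mask = rr < radius_nm
    patch = np.zeros_like(rr)
    patch[mask] = amplitude_nm * np.cos(np.pi * rr[mask] / (2.0 * radius_nm))
    grid[r0:r1, c0:c1] += patch


def render_height_frame(events: Sequence[EventSpec], frame: int,
                        cfg: SimulationConfig,
                        cum_drift_nm: np.ndarray | None = None,
                        background: np.ndarray | None = None) -> np.ndarray:
    """Render the clean (pre-tip, pre-artifact) height grid of one frame."""
    if not 0 <= frame < cfg.n_frames:
        raise ValueError(f"frame {frame} outside movie of {cfg.n_frames} frames")
    grid = (np.zeros(cfg.grid_shape) if background is None
            else background.astype(float, copy=True))
    drift = (np.zeros(2) if cum_drift_nm is None
             else np.asarray(cum_drift_nm, dtype=float))
    depth = cfg.geometry.pit_depth_nm
    for ev in events:
        pos = ev.trajectory_nm[frame] + drift
        if ev.is_open(frame):
            radius = ev.aperture_nm[frame] / 2.0
            _add_radial(grid, cfg.pixel_size_nm, tuple(pos), radius, -depth)
        sw = ev.swelling
        if sw is not None:
            factor = sw.height_factor(frame)
            if factor > 0:
                off = sw.center_offset(frame, ev.max_aperture_nm / 2.0)
                center = (pos[0] + off[0], pos[1] + off[1])
                _add_radial(grid, cfg.pixel_size_nm, center,
                            sw.diameter_nm / 2.0, factor * sw.height_nm)
    return grid


# ---------------------------------------------------------------------------
# tip convolution
# ---------------------------------------------------------------------------

def tip_structure(tip_radius_nm: float, pixel_size_nm: float) -> np.ndarray:
    """Spherical-cap structure function sampled on the pixel grid.

    Values are the (non-positive) height of the inverted tip apex surface;
    positions outside the tip footprint get a large negative sentinel so
    they never win the dilation maximum.
    """
    rpx = int(np.floor(tip_radius_nm / pixel_size_nm))
    size = 2 * rpx + 1
    coords = (np.arange(size) - rpx) * pixel_size_nm
    rr2 = coords[None, :] ** 2 + coords[:, None] ** 2
    struct = np.full((size, size), -1.0e9)
    inside = rr2 <= tip_radius_nm ** 2
    struct[inside] = np.sqrt(tip_radius_nm ** 2 - rr2[inside]) - tip_radius_nm
    return struct


def apply_tip_convolution(grid: np.ndarray, tip_radius_nm: float,
                          pixel_size_nm: float) -> np.ndarray:
    """Image a surface with a spherical-cap tip (grayscale dilation).

    The output is everywhere >= the input and equals it for a zero-radius
    (ideally sharp) tip.
    """
    if tip_radius_nm < 0:
        raise ValueError("tip radius must be >= 0")
    half_extent = min(grid.shape) * pixel_size_nm / 2.0
    if tip_radius_nm > half_extent:
        raise ValueError("tip radius exceeds half the grid extent")
    struct = tip_structure(tip_radius_nm, pixel_size_nm)
    if struct.shape == (1, 1):
        return grid.astype(float, copy=True)
    return ndimage.grey_dilation(grid.astype(float), structure=struct,
                                 mode="nearest")


# ---------------------------------------------------------------------------
# scan artifacts
# ---------------------------------------------------------------------------

def apply_tip_skip(grid: np.ndarray, row: int, width: int,
                   offset_nm: float) -> np.ndarray:
    """Replace ``width`` consecutive rows by the previous row plus an offset."""
    out = grid.copy()
    width = min(width, grid.shape[0] - row)
    out[row:row + width] = grid[row - 1] + offset_nm
    return out


def inject_scan_artifacts(grid: np.ndarray, artifact_rates, rng: np.random.Generator,
                          frame: int = 0) -> tuple[np.ndarray, list[dict[str, Any]]]:
    """Stochastically inject tip-skip lines and amplitude steps.

    Tip skips hit 1-2 consecutive scan lines (~19-37 nm at the default
    18.75 nm pixel); amplitude steps rescale the texture contrast, the
    signature of a changed cantilever drive amplitude.
    """
    log: list[dict[str, Any]] = []
    out = grid
    if rng.uniform() < artifact_rates.tip_skip_per_frame and grid.shape[0] > 2:
        row = int(rng.integers(1, grid.shape[0] - 1))
        width = int(rng.integers(1, 3))
        offset = float(rng.uniform(5.0, 15.0))
        out = apply_tip_skip(out, row, width, offset)
        log.append({"frame": frame, "type": "tip_skip",
                    "rows": list(range(row, min(row + width, grid.shape[0]))),
                    "offset_nm": offset})
    if rng.uniform() < artifact_rates.amplitude_step_per_frame:
        factor = float(rng.uniform(1.05, 1.2))
        med = np.median(out)
        out = med + (out - med) * factor
        log.append({"frame": frame, "type": "amplitude_step", "factor": factor})
    if out is grid:
        out = grid.copy()
    return out, log


# ---------------------------------------------------------------------------
# fluorescence
# ---------------------------------------------------------------------------

def optical_grid_shape(cfg: SimulationConfig, pad_px: int = 6) -> tuple[int, int]:
    width, height = cfg.scan_extent_nm
    return (int(np.ceil(height / cfg.optical_pixel_nm)) + 2 * pad_px,
            int(np.ceil(width / cfg.optical_pixel_nm)) + 2 * pad_px)


def scan_to_optical_px(xy_nm: np.ndarray, cfg: SimulationConfig,
                       pad_px: int = 6) -> np.ndarray:
    """Map scan-local nm coordinates to (col, row) optical pixel coordinates."""
    xy = np.asarray(xy_nm, dtype=float)
    return xy / cfg.optical_pixel_nm + pad_px - 0.5


def render_fluor_frame(events: Sequence[EventSpec], frame: int, channel: str,
                       traces: dict[int, np.ndarray], cfg: SimulationConfig,
                       cum_drift_nm: np.ndarray | None,
                       rng: np.random.Generator, pad_px: int = 6) -> np.ndarray:
    """Render one fluorescence frame (uint16) with Poisson + read noise.

    ``traces`` maps event id -> per-frame normalised amplitude for this
    channel.  Spots are 2-D Gaussians of the configured PSF width whose
    integrated intensity at trace maximum is ``noise.photon_scale``.
    """
    shape = optical_grid_shape(cfg, pad_px)
    opx = cfg.optical_pixel_nm
    sigma_px = cfg.psf_sigma_nm / opx
    peak = cfg.noise.photon_scale / (2.0 * np.pi * sigma_px ** 2)
    photons = np.full(shape, cfg.noise.background_photons, dtype=float)
    drift = (np.zeros(2) if cum_drift_nm is None
             else np.asarray(cum_drift_nm, dtype=float))
    half = int(np.ceil(4 * sigma_px))
    for ev in events:
        amp = traces.get(ev.event_id)
        if amp is None or amp[frame] <= 0:
            continue
        cx, cy = scan_to_optical_px(ev.trajectory_nm[frame] + drift, cfg, pad_px)
        c0, c1 = max(0, int(cx) - half), min(shape[1], int(cx) + half + 1)
        r0, r1 = max(0, int(cy) - half), min(shape[0], int(cy) + half + 1)
        if c0 >= c1 or r0 >= r1:
            continue
        xs = np.arange(c0, c1) - cx
        ys = np.arange(r0, r1) - cy
        g = np.exp(-(xs[None, :] ** 2 + ys[:, None] ** 2) / (2 * sigma_px ** 2))
        photons[r0:r1, c0:c1] += peak * amp[frame] * g
    counts = rng.poisson(photons).astype(float)
    if cfg.noise.read_noise > 0:
        counts += rng.normal(0.0, cfg.noise.read_noise, size=shape)
    return np.clip(np.round(counts), 0, 65535).astype(np.uint16)
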