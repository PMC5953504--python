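"""Brownian pit trajectories with optional stage drift.

Pit centres move by 2-D isotropic Brownian motion: each per-frame step is
drawn from a Gaussian with variance 2*D*dt per axis (MSD = 4*D*dt in 2-D),
plus a deterministic drift vector per frame.
"""

from __future__ import annotations

import numpy as np

from .config import NM2_PER_CM2


def cm2_to_nm2(d_cm2_s: float) -> float:
    """Convert a diffusion coefficient from cm^2/s to nm^2/s."""
    return d_cm2_s * NM2_PER_CM2


def nm2_to_cm2(d_nm2_s: float) -> float:
    """Convert a diffusion coefficient from nm^2/s to cm^2/s."""
    return d_nm2_s / NM2_PER_CM2


def sample_trajectory(
    d_cm2_s: float,
    drift_nm_per_frame: tuple[float, float],
    n_frames: int,
    dt_s: float,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Sample per-frame (x, y) positions in nm, starting at the origin.

    Parameters
    ----------
    d_cm2_s
        Diffusion coefficient in cm^2/s.
    drift_nm_per_frame
        Deterministic displacement added to every step (nm/frame).
    n_frames
        Number of positions returned (>= 1).
    dt_s
        Frame interval in seconds.
    rng
        Seed or Generator; required for reproducibility.

    Returns
    -------
    (n_frames, 2) float array of positions in nm; ``positions[0]`` is (0, 0).
    """
    if d_cm2_s < 0:
        raise ValueError("diffusion coefficient must be >= 0")
    if dt_s <= 0:
        raise ValueError("frame interval must be > 0")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(rng)
    sigma = np.sqrt(2.0 * cm2_to_nm2(d_cm2_s) * dt_s)
    steps = rng.normal(0.0, sigma, size=(n_frames - 1, 2))
    steps += np.asarray(drift_nm_per_frame, dtype=float)
    positions = np.zeros((n_frames, 2))
    np.cumsum(steps, axis=0, out=positions[1:])
    return positions
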