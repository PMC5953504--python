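"""Drift estimation and MSD-based diffusion coefficients.

Specimen drift is estimated from the tracked pits themselves: the
average displacement of randomly diffusing objects is zero, so the
ensemble-mean displacement of all pits between frames is the stage
drift.  Tracks are drift-corrected and time-averaged mean squared
displacements fitted over the first few lags (MSD = 4 D t in 2-D).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajectory import nm2_to_cm2
from .tracking import PitTrack


class InsufficientDataError(ValueError):
    pass


@dataclass
class DriftEstimate:
    cum_drift_nm: np.ndarray        # (n_frames, 2); [0] == (0, 0)
    method: str
    n_tracks: int

    def at(self, frame: int) -> np.ndarray:
        return self.cum_drift_nm[frame]


@dataclass
class MSDCurve:
    lag_s: np.ndarray
    msd_nm2: np.ndarray
    counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lag_s": self.lag_s, "msd_nm2": self.msd_nm2,
                             "n": self.counts})


@dataclass
class DiffusionEstimate:
    d_cm2_s: float
    se_cm2_s: float
    n_lags: int
    negative_slope: bool = False
    identity: str = "all"


def estimate_drift(tracks: list[PitTrack], n_frames: int,
                   method: str = "ensemble") -> DriftEstimate:
    """Cumulative per-frame drift from the track ensemble.

    ``ensemble``: mean displacement of all tracks present in each
    consecutive frame pair, accumulated (handles non-uniform drift).
    ``first-last``: the mean displacement of each track between its
    first and last detection, spread uniformly over the movie — the
    classic initial-vs-final estimate.
    """
    usable = [t for t in tracks if len(t.detections) >= 2]
    if not usable:
        raise InsufficientDataError("no track spans two frames")
    if method == "first-last":
        net = np.zeros(2)
        rate = np.zeros(2)
        for t in usable:
            span = t.last_frame - t.first_frame
            disp = t.positions_nm[-1] - t.positions_nm[0]
            net += disp
            rate += disp / span
        rate /= len(usable)
        cum = np.outer(np.arange(n_frames), rate)
        return DriftEstimate(cum_drift_nm=cum, method=method,
                             n_tracks=len(usable))
    if method != "ensemble":
        raise ValueError(f"unknown drift method {method!r}")

    steps = np.zeros((n_frames, 2))
    for f in range(1, n_frames):
        disps = []
        for t in usable:
            frames = t.frames
            i = np.searchsorted(frames, f - 1)
            j = np.searchsorted(frames, f)
            if (i < len(frames) and frames[i] == f - 1
                    and j < len(frames) and frames[j] == f):
                disps.append(t.positions_nm[j] - t.positions_nm[i])
        if disps:
            steps[f] = np.mean(disps, axis=0)
    cum = np.cumsum(steps, axis=0)
    return DriftEstimate(cum_drift_nm=cum, method="ensemble",
                         n_tracks=len(usable))


def net_displacement_nm(tracks: list[PitTrack]) -> np.ndarray:
    """Ensemble-mean displacement vector between each track's first and
    last detection (the drift statistic; ~0 for drift-free diffusion)."""
    usable = [t for t in tracks if len(t.detections) >= 2]
    if not usable:
        raise InsufficientDataError("no track spans two frames")
    return np.mean([t.positions_nm[-1] - t.positions_nm[0] for t in usable],
                   axis=0)


def _pair_sums(track: PitTrack, drift: DriftEstimate | None,
               dt_s: float) -> dict[int, tuple[float, int]]:
    """Sum of squared displacements and pair counts per integer lag."""
    frames = track.frames
    pos = track.positions_nm.copy()
    if drift is not None:
        pos = pos - drift.cum_drift_nm[frames]
    sums: dict[int, tuple[float, int]] = {}
    n = len(frames)
    for i in range(n - 1):
        for j in range(i + 1, n):
            lag = int(frames[j] - frames[i])
            sq = float(np.sum((pos[j] - pos[i]) ** 2))
            s, c = sums.get(lag, (0.0, 0))
            sums[lag] = (s + sq, c + 1)
    return sums


def compute_msd(track: PitTrack, drift: DriftEstimate | None = None,
                dt_s: float = 10.0) -> MSDCurve:
    """Time-averaged MSD of one drift-corrected track."""
    if len(track.detections) < 2:
        raise InsufficientDataError("track needs at least 2 detections")
    sums = _pair_sums(track, drift, dt_s)
    lags = np.array(sorted(sums), dtype=int)
    msd = np.array([sums[l][0] / sums[l][1] for l in lags])
    counts = np.array([sums[l][1] for l in lags])
    return MSDCurve(lag_s=lags * dt_s, msd_nm2=msd, counts=counts)


def ensemble_msd(tracks: list[PitTrack], drift: DriftEstimate | None = None,
                 dt_s: float = 10.0, min_open_frames: int = 5) -> MSDCurve:
    """Pair-weighted ensemble MSD over all sufficiently long tracks."""
    total: dict[int, tuple[float, int]] = {}
    n_used = 0
    for t in tracks:
        if len(t.detections) < min_open_frames:
            continue
        n_used += 1
        for lag, (s, c) in _pair_sums(t, drift, dt_s).items():
            s0, c0 = total.get(lag, (0.0, 0))
            total[lag] = (s0 + s, c0 + c)
    if not total:
        raise InsufficientDataError("no usable tracks for the ensemble MSD")
    lags = np.array(sorted(total), dtype=int)
    msd = np.array([total[l][0] / total[l][1] for l in lags])
    counts = np.array([total[l][1] for l in lags])
    return MSDCurve(lag_s=lags * dt_s, msd_nm2=msd, counts=counts)


def fit_diffusion(msd: MSDCurve, n_lags: int = 4, min_counts: int = 10,
                  identity: str = "all") -> DiffusionEstimate:
    """Zero-intercept least-squares fit of MSD = 4 D t over the first lags."""
    ok = msd.counts >= min_counts
    lags = msd.lag_s[ok][:n_lags]
    vals = msd.msd_nm2[ok][:n_lags]
    if len(lags) < n_lags:
        raise InsufficientDataError(
            f"need {n_lags} lags with >= {min_counts} pairs, have {len(lags)}")
    denom = float(np.sum(lags ** 2))
    slope = float(np.sum(lags * vals)) / denom       # nm^2/s
    resid = vals - slope * lags
    dof = max(1, len(lags) - 1)
    slope_se = float(np.sqrt(np.sum(resid ** 2) / dof / denom))
    negative = slope < 0
    d_nm2 = max(0.0, slope) / 4.0
    return DiffusionEstimate(d_cm2_s=nm2_to_cm2(d_nm2),
                             se_cm2_s=nm2_to_cm2(slope_se / 4.0),
                             n_lags=len(lags), negative_slope=negative,
                             identity=identity)
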