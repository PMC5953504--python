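"""Phase segmentation of fluorescence traces and protein-timing statistics.

The clathrin intensity time course of an endocytic event is divided into
growing / stable / closing phases by a slope criterion: after
max-normalisation and 3-frame smoothing, the *stable* phase is the
earliest run of more than 4 consecutive frames whose per-frame slope
lies within [-0.05, +0.1]; growing and closing are the periods before
and after.  Channel appearance/peak/disappearance times are reported
relative to two AFM-derived anchors: the start of membrane invagination
and the completed closure of the pit (both t = 0 conventions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .movio import FluorMovie
from .registration import RegistrationTransform, spot_centroid
from .tracking import PitTrack

SLOPE_BAND = (-0.05, 0.1)


class NoSignalError(ValueError):
    """Trace carries no signal to segment."""


@dataclass
class IntensityTrace:
    """Background-subtracted per-frame intensity of one event/channel."""

    event_id: int
    channel: str
    values: np.ndarray
    frame_interval_s: float
    start_frame: int = 0            # movie frame of values[0]
    noise_sigma: float = 0.0        # background noise SD of `values`
    normalization: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) < 1:
            raise ValueError("trace must be a non-empty 1-D array")

    def normalized(self) -> np.ndarray:
        m = self.values.max()
        if m <= 0:
            raise NoSignalError("all-zero trace")
        return self.values / m


@dataclass
class PhaseSegmentation:
    signal_start: int               # frame indices into the trace
    signal_end: int
    stable_start: int
    stable_end: int
    stable_empty: bool
    frame_interval_s: float
    smoothed: np.ndarray
    slopes: np.ndarray

    @property
    def growing_s(self) -> float:
        return (self.stable_start - self.signal_start) * self.frame_interval_s

    @property
    def stable_s(self) -> float:
        if self.stable_empty:
            return 0.0
        return (self.stable_end - self.stable_start) * self.frame_interval_s

    @property
    def closing_s(self) -> float:
        return (self.signal_end - self.stable_end) * self.frame_interval_s


def smooth_3frame(values: np.ndarray) -> np.ndarray:
    """Centered 3-frame moving average; the window shrinks at the edges."""
    v = np.asarray(values, dtype=float)
    out = v.copy()
    if len(v) >= 3:
        out[1:-1] = (v[:-2] + v[1:-1] + v[2:]) / 3.0
        out[0] = (v[0] + v[1]) / 2.0
        out[-1] = (v[-2] + v[-1]) / 2.0
    elif len(v) == 2:
        out[:] = v.mean()
    return out


def central_slopes(values: np.ndarray) -> np.ndarray:
    """Per-frame slope, central differences (one-sided at the edges)."""
    v = np.asarray(values, dtype=float)
    out = np.empty_like(v)
    if len(v) == 1:
        out[:] = 0.0
        return out
    out[1:-1] = (v[2:] - v[:-2]) / 2.0
    out[0] = v[1] - v[0]
    out[-1] = v[-1] - v[-2]
    return out


def segment_phases(trace: IntensityTrace,
                   slope_band: tuple[float, float] = SLOPE_BAND,
                   min_stable_frames: int = 5,
                   signal_threshold: float = 0.02) -> PhaseSegmentation:
    """Segment a trace into growing / stable / closing phases.

    Segmentation operates on the max-normalised trace, so it is
    invariant to positive rescaling of the raw intensities.  When no
    slope run of at least ``min_stable_frames`` qualifies, the stable
    phase is empty and growing/closing split at the smoothed argmax.
    """
    if len(trace.values) < 6:
        raise ValueError("trace shorter than 6 frames cannot be segmented")
    norm = trace.normalized()
    smoothed = smooth_3frame(norm)
    slopes = central_slopes(smoothed)

    # the signal interval is delimited on the smoothed trace with a
    # noise-aware threshold so background flicker cannot stretch it
    thr = max(signal_threshold, 3.0 * trace.noise_sigma / trace.values.max())
    above = np.flatnonzero(smoothed > thr)
    if above.size == 0:
        raise NoSignalError("trace never rises above the signal threshold")
    sig0, sig1 = int(above[0]), int(above[-1])

    lo, hi = slope_band
    ok = (slopes >= lo) & (slopes <= hi)
    ok[:sig0] = False
    ok[sig1 + 1:] = False

    stable_start = stable_end = -1
    run_start = None
    for i in range(sig0, sig1 + 1):
        if ok[i]:
            if run_start is None:
                run_start = i
        else:
            if run_start is not None and i - run_start >= min_stable_frames:
                stable_start, stable_end = run_start, i - 1
                break
            run_start = None
    if stable_start < 0 and run_start is not None \
            and sig1 + 1 - run_start >= min_stable_frames:
        stable_start, stable_end = run_start, sig1

    if stable_start < 0:
        split = sig0 + int(np.argmax(smoothed[sig0:sig1 + 1]))
        return PhaseSegmentation(signal_start=sig0, signal_end=sig1,
                                 stable_start=split, stable_end=split,
                                 stable_empty=True,
                                 frame_interval_s=trace.frame_interval_s,
                                 smoothed=smoothed, slopes=slopes)
    return PhaseSegmentation(signal_start=sig0, signal_end=sig1,
                             stable_start=stable_start, stable_end=stable_end,
                             stable_empty=False,
                             frame_interval_s=trace.frame_interval_s,
                             smoothed=smoothed, slopes=slopes)


# ---------------------------------------------------------------------------
# AFM anchors
# ---------------------------------------------------------------------------

def detect_event_times(track: PitTrack, n_frames: int,
                       dt_s: float) -> tuple[float, float | None]:
    """(t0_invagination, t0_closure) of a track in seconds.

    Invagination starts at the first frame of the first run of two or
    more consecutive detections; closure is the first detection-free
    frame after the final open frame, or None (censored) when the track
    is still open at the movie end.
    """
    if len(track.detections) < 2:
        raise ValueError("track must have at least 2 detections")
    frames = track.frames
    t_inv = None
    for i in range(len(frames) - 1):
        if frames[i + 1] == frames[i] + 1:
            t_inv = frames[i] * dt_s
            break
    if t_inv is None:
        t_inv = frames[0] * dt_s
    closure = track.closure_frame(n_frames)
    t_clo = closure * dt_s if closure is not None else None
    return float(t_inv), t_clo


# ---------------------------------------------------------------------------
# channel timing relative to the anchors
# ---------------------------------------------------------------------------

@dataclass
class EventTimes:
    event_id: int
    channel: str
    appearance_s: float
    peak_s: float
    disappearance_s: float
    vs_invagination: dict[str, float] = field(default_factory=dict)
    vs_closure: dict[str, float] = field(default_factory=dict)


class ChannelAbsentError(ValueError):
    """Trace never exceeds the detection threshold."""


def _threshold_runs(above: np.ndarray, min_run: int = 2) -> tuple[int, int] | None:
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return None
    first = last = None
    run = 1
    for i in range(1, len(idx)):
        run = run + 1 if idx[i] == idx[i - 1] + 1 else 1
        if run >= min_run and first is None:
            first = idx[i] - min_run + 1
    run = 1
    for i in range(len(idx) - 2, -1, -1):
        run = run + 1 if idx[i] == idx[i + 1] - 1 else 1
        if run >= min_run and last is None:
            last = idx[i] + min_run - 1
    if first is None or last is None:
        return None
    return int(first), int(last)


def relative_timing(trace: IntensityTrace, t0_invagination_s: float,
                    t0_closure_s: float | None, threshold_k: float = 3.0,
                    min_run: int = 2) -> EventTimes:
    """Appearance / peak / disappearance of a channel vs the AFM anchors.

    Appearance (disappearance) is the first (last) of at least
    ``min_run`` consecutive frames whose background-subtracted intensity
    exceeds ``threshold_k`` background sigmas; the peak is the argmax of
    the smoothed trace.
    """
    dt = trace.frame_interval_s
    thr = threshold_k * trace.noise_sigma
    runs = _threshold_runs(trace.values > thr, min_run)
    if runs is None:
        raise ChannelAbsentError(
            f"channel {trace.channel!r} absent for event {trace.event_id}")
    first, last = runs
    smoothed = smooth_3frame(trace.values)
    peak = first + int(np.argmax(smoothed[first:last + 1]))
    t_app = (trace.start_frame + first) * dt
    t_peak = (trace.start_frame + peak) * dt
    t_dis = (trace.start_frame + last) * dt
    ev = EventTimes(event_id=trace.event_id, channel=trace.channel,
                    appearance_s=t_app, peak_s=t_peak, disappearance_s=t_dis)
    ev.vs_invagination = {"appearance": t_app - t0_invagination_s,
                          "peak": t_peak - t0_invagination_s,
                          "disappearance": t_dis - t0_invagination_s}
    if t0_closure_s is not None:
        ev.vs_closure = {"appearance": t_app - t0_closure_s,
                         "peak": t_peak - t0_closure_s,
                         "disappearance": t_dis - t0_closure_s}
    return ev


def timing_summary(event_times: list[EventTimes]) -> pd.DataFrame:
    """Cohort mean +- SD of the timing offsets, per channel and anchor."""
    rows = []
    for ev in event_times:
        for anchor, offsets in (("invagination", ev.vs_invagination),
                                ("closure", ev.vs_closure)):
            for what, off in offsets.items():
                rows.append({"channel": ev.channel, "anchor": anchor,
                             "what": what, "offset_s": off})
    if not rows:
        return pd.DataFrame(columns=["channel", "anchor", "what",
                                     "mean_s", "sd_s", "n"])
    df = pd.DataFrame(rows)
    out = (df.groupby(["channel", "anchor", "what"])["offset_s"]
             .agg(mean_s="mean", sd_s="std", n="count").reset_index())
    return out


# ---------------------------------------------------------------------------
# trace extraction from fluorescence movies
# ---------------------------------------------------------------------------

def extract_trace(movie: FluorMovie, track: PitTrack,
                  transform: RegistrationTransform, psf_sigma_nm: float = 106.0,
                  pre_frames: int = 8, post_frames: int = 8) -> IntensityTrace:
    """Matched-filter intensity trace of a track in one channel.

    Follows the track position (held at the nearest detection through
    gaps and for a margin before birth / after closure, to catch early
    assembly and post-closure residence) and estimates the spot
    amplitude each frame with a sub-pixel Gaussian matched filter after
    local-median background subtraction — insensitive to the spot
    drifting across pixel boundaries.
    """
    n_frames = movie.frames.shape[0]
    first = max(0, track.first_frame - pre_frames)
    last = min(n_frames - 1, track.last_frame + post_frames)
    frames = track.frames
    pos = track.positions_nm
    sigma_px = psf_sigma_nm / movie.pixel_size_nm
    w = int(np.ceil(3 * sigma_px))

    def to_px(xy_nm: np.ndarray) -> np.ndarray:
        return transform.nm_to_optical_px(transform.scanlocal_to_nm(xy_nm))

    def refine(f: int, guess: np.ndarray, max_step_px: float) -> np.ndarray:
        res = spot_centroid(movie.frames[f], tuple(guess),
                            window_px=max(2, w - 1))
        if res is None:
            return guess
        cand = np.array(res[0])
        return cand if np.hypot(*(cand - guess)) <= max_step_px else guess

    # anchor positions: inside the track, linear interpolation between the
    # AFM detections (sub-pixel accurate, covers re-opening gaps, and
    # immune to overlapping neighbour spots); outside it, follow the spot
    # frame by frame with a small-step refinement chain whose total
    # excursion from the track end is bounded
    anchors = np.zeros((last - first + 1, 2))
    span = range(max(first, track.first_frame),
                 min(last, track.last_frame) + 1)
    for f in span:
        x = np.interp(f, frames, pos[:, 0])
        y = np.interp(f, frames, pos[:, 1])
        anchors[f - first] = to_px(np.array([x, y]))

    def chain(start_anchor: np.ndarray, frame_iter) -> None:
        guess = start_anchor
        for f in frame_iter:
            cand = refine(f, guess, 2.5)
            if np.hypot(*(cand - start_anchor)) <= 6.0:
                guess = cand
            anchors[f - first] = guess

    chain(anchors[track.first_frame - first],
          range(track.first_frame - 1, first - 1, -1))
    chain(anchors[min(last, track.last_frame) - first],
          range(track.last_frame + 1, last + 1))

    values = np.zeros(last - first + 1)
    sigmas = np.zeros_like(values)
    for k, f in enumerate(range(first, last + 1)):
        col, row = anchors[k]
        c, r = int(round(col)), int(round(row))
        img = movie.frames[f].astype(float)
        rows_n, cols_n = img.shape
        c0, c1 = max(0, c - w), min(cols_n, c + w + 1)
        r0, r1 = max(0, r - w), min(rows_n, r + w + 1)
        if c1 - c0 < 2 or r1 - r0 < 2:
            continue
        R = w + 4
        rc0, rc1 = max(0, c - R), min(cols_n, c + R + 1)
        rr0, rr1 = max(0, r - R), min(rows_n, r + R + 1)
        ring = img[rr0:rr1, rc0:rc1].copy()
        ring[r0 - rr0:r1 - rr0, c0 - rc0:c1 - rc0] = np.nan
        bg = float(np.nanmedian(ring))
        mad = float(np.nanmedian(np.abs(ring - bg)))
        xs = np.arange(c0, c1) - col
        ys = np.arange(r0, r1) - row
        g = np.exp(-(xs[None, :] ** 2 + ys[:, None] ** 2)
                   / (2 * sigma_px ** 2))
        g2 = float((g ** 2).sum())
        values[k] = float((g * (img[r0:r1, c0:c1] - bg)).sum()) / g2
        sigmas[k] = 1.4826 * mad / np.sqrt(g2)
    return IntensityTrace(event_id=track.track_id, channel=movie.channel,
                          values=values, frame_interval_s=movie.frame_interval_s,
                          start_frame=first,
                          noise_sigma=float(np.median(sigmas[sigmas > 0]))
                          if np.any(sigmas > 0) else 0.0)
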