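"""Fluorescence intensity traces for simulated events.

A trace is a piecewise-linear time course anchored on the event's
appearance, peak and disappearance times, normalised to its maximum.
The rise has a small nucleation step followed by a fast linear climb to
~0.9 of the maximum and a slow final approach to the peak, so that the
slope-band phase criterion (stable when the per-frame slope of the
smoothed, max-normalised trace is within [-0.05, +0.1]) produces
well-defined growing/stable/closing segments.  Re-opening events carry
the characteristic partial loss of clathrin during the closed gap
(retention drawn around 39% of the maximum) followed by re-assembly.
"""

from __future__ import annotations

import numpy as np

from .config import SimulationConfig
from .events import EventSpec, CAVEOLA


class TraceConfigurationError(ValueError):
    """Raised when a channel has no timing parameters for an event."""


def _anchors(event: EventSpec, channel: str, dt: float) -> tuple[np.ndarray, np.ndarray]:
    t_app, t_peak, t_disapp = event.channel_times_s[channel]
    pts: list[tuple[float, float]] = [(t_app - 1e-9, 0.0), (t_app, 0.18)]

    reopen = (channel == "clathrin" and event.reopen_gap_frames is not None
              and event.reopen_retention is not None)
    if reopen:
        g0, g1 = event.reopen_gap_frames
        t_gap, t_reopen = g0 * dt, g1 * dt
        rise_end = min(t_app + np.clip(0.3 * (t_gap - t_app), 2 * dt, 4 * dt),
                       t_gap - 0.5 * dt)
        if rise_end > t_app:
            pts.append((rise_end, 0.9))
        pts.append((t_gap, 1.0))
        pts.append((t_reopen, event.reopen_retention))
        pts.append((t_reopen + 2 * dt, 0.9))
        pts.append((max(t_peak, t_reopen + 2.5 * dt), 0.95))
        pts.append((t_disapp, 0.0))
    else:
        rise_end = min(t_app + np.clip(0.3 * (t_peak - t_app), 2 * dt, 4 * dt),
                       t_peak - 0.5 * dt)
        if rise_end > t_app:
            pts.append((rise_end, 0.8))
        # plateau with a pronounced final climb so the trace maximum is
        # well defined against photon noise
        if t_peak - 2.5 * dt > rise_end:
            pts.append((t_peak - 2.5 * dt, 0.85))
        pts.append((t_peak, 1.0))
        # near-symmetric shoulders around the maximum (so smoothing does
        # not displace it) and a terminal step: the coat is released over
        # roughly a frame once disassembly completes
        if t_peak + 2.5 * dt < t_disapp:
            pts.append((t_peak + 2.5 * dt, 0.8))
        pts.append((t_disapp, 0.15))
    pts.append((t_disapp + 1e-9, 0.0))

    pts.sort(key=lambda p: p[0])
    t = np.array([p[0] for p in pts])
    v = np.array([p[1] for p in pts])
    keep = np.concatenate([[True], np.diff(t) > 0])
    return t[keep], v[keep]


def synthesize_trace(event: EventSpec, channel: str, cfg: SimulationConfig,
                     n_frames: int | None = None,
                     lag_s: float = 0.0) -> np.ndarray:
    """Noise-free per-frame trace amplitude in [0, 1] for one channel.

    ``lag_s`` shifts the sampling comb to model the unsynchronised
    AFM/CLSM controllers: fluorescence frame ``k`` integrates around time
    ``k * dt + lag_s`` but is indexed at frame ``k``.
    """
    if channel not in cfg.timing:
        raise TraceConfigurationError(
            f"channel {channel!r} has no timing parameters")
    if channel not in event.channel_times_s:
        raise TraceConfigurationError(
            f"event {event.event_id} carries no times for channel {channel!r}")
    n = cfg.n_frames if n_frames is None else n_frames
    dt = cfg.frame_interval_s
    t_samples = np.arange(n) * dt + lag_s

    if event.identity == CAVEOLA:
        # caveolae persist for the whole movie with a steady marker signal
        return np.ones(n)

    t, v = _anchors(event, channel, dt)
    trace = np.interp(t_samples, t, v, left=0.0, right=0.0)
    m = trace.max()
    if m > 0:
        trace = trace / m
    return trace
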