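"""End-to-end synthetic dataset generation.

``generate_dataset`` composes the event sampler, trace synthesiser and
frame renderers into a :class:`MovieBundle`: an AFM height movie, one
fluorescence movie per configured channel, and the ground truth needed
to score the analysis chain.  Output is a pure function of the
configuration (including its seed).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .config import SimulationConfig
from .events import EventSpec, GroundTruth, sample_events
from .movio import FluorMovie, HeightMovie, write_movie
from .render import (apply_tip_convolution, background_field,
                     inject_scan_artifacts, optical_grid_shape,
                     render_fluor_frame, render_height_frame)
from .traces import synthesize_trace


@dataclass
class MovieBundle:
    height: HeightMovie
    fluor: dict[str, FluorMovie]
    truth: GroundTruth
    config: SimulationConfig

    @property
    def n_frames(self) -> int:
        return self.height.n_frames


def clean_traces(events: list[EventSpec], channel: str, cfg: SimulationConfig,
                 lag_s: float = 0.0) -> dict[int, np.ndarray]:
    """Noise-free per-event traces for one channel (event id -> array)."""
    out: dict[int, np.ndarray] = {}
    for ev in events:
        if channel in ev.channel_times_s or ev.identity == "caveola":
            out[ev.event_id] = synthesize_trace(ev, channel, cfg, lag_s=lag_s)
    return out


def _phase_truth(events: list[EventSpec], cfg: SimulationConfig,
                 lag_s: float = 0.0) -> None:
    """Attach operational phase boundaries to each event.

    Phases are defined by the slope-band criterion itself, so the ground
    truth is the criterion applied to the noise-free clathrin trace.
    """
    from .lifecycle import IntensityTrace, segment_phases

    if "clathrin" not in cfg.channels:
        return
    for ev in events:
        if ev.identity != "CCP" or "clathrin" not in ev.channel_times_s:
            continue
        trace = synthesize_trace(ev, "clathrin", cfg, lag_s=lag_s)
        if trace.max() <= 0:
            continue
        seg = segment_phases(IntensityTrace(
            event_id=ev.event_id, channel="clathrin", values=trace,
            frame_interval_s=cfg.frame_interval_s))
        ev.phase_truth_frames = {
            "clathrin": (seg.signal_start, seg.stable_start,
                         seg.stable_end, seg.signal_end)}


def generate_dataset(cfg: SimulationConfig, outdir: str | None = None) -> MovieBundle:
    """Generate a paired AFM + fluorescence bundle with ground truth.

    Identical configurations (same seed) produce bit-identical bundles.
    When ``outdir`` is given the stacks, ground truth, and a config echo
    are also written to disk.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    ev_rng, bg_rng, art_rng, fl_rng = rng.spawn(4)

    events = sample_events(cfg, ev_rng)
    cum_drift = np.outer(np.arange(cfg.n_frames),
                         np.asarray(cfg.drift_velocity_nm, dtype=float))
    time_lag = float(rng.uniform(0.0, cfg.frame_interval_s))

    # AFM stack
    height_frames = np.empty((cfg.n_frames, *cfg.grid_shape), dtype=np.float32)
    artifact_log: list[dict] = []
    for t in range(cfg.n_frames):
        bg = background_field(cfg.grid_shape, cfg.noise.roughness_nm,
                              cfg.noise.corr_length_nm, cfg.pixel_size_nm, bg_rng)
        frame = render_height_frame(events, t, cfg, cum_drift[t], bg)
        frame = apply_tip_convolution(frame, cfg.tip_radius_nm, cfg.pixel_size_nm)
        frame, log = inject_scan_artifacts(frame, cfg.artifact_rates, art_rng, t)
        artifact_log.extend(log)
        height_frames[t] = frame
    height = HeightMovie(frames=height_frames,
                         frame_interval_s=cfg.frame_interval_s,
                         pixel_size_nm=cfg.pixel_size_nm,
                         artifact_log=artifact_log)

    # fluorescence stacks
    fluor: dict[str, FluorMovie] = {}
    for ch in cfg.channels:
        traces = clean_traces(events, ch, cfg, lag_s=time_lag)
        # channel markers only decorate their own identity class
        if ch == "caveolin":
            traces = {ev.event_id: traces[ev.event_id] for ev in events
                      if ev.identity == "caveola" and ev.event_id in traces}
        else:
            traces = {ev.event_id: traces[ev.event_id] for ev in events
                      if ev.identity == "CCP" and ev.event_id in traces}
        frames = np.empty((cfg.n_frames, *optical_grid_shape(cfg)),
                          dtype=np.uint16)
        for t in range(cfg.n_frames):
            frames[t] = render_fluor_frame(events, t, ch, traces, cfg,
                                           cum_drift[t], fl_rng)
        fluor[ch] = FluorMovie(frames=frames,
                               frame_interval_s=cfg.frame_interval_s,
                               pixel_size_nm=cfg.optical_pixel_nm, channel=ch)

    _phase_truth(events, cfg, lag_s=time_lag)
    truth = GroundTruth(events=events, cum_drift_nm=cum_drift,
                        artifact_log=artifact_log, time_lag_s=time_lag)
    bundle = MovieBundle(height=height, fluor=fluor, truth=truth, config=cfg)

    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        meta = {"scan_corners_um": [[-3.0, 2.25], [3.0, 2.25],
                                    [3.0, -2.25], [-3.0, -2.25]]}
        write_movie(height, os.path.join(outdir, "afm_height.tif"), meta)
        for ch, mv in fluor.items():
            write_movie(mv, os.path.join(outdir, f"fluor_{ch}.tif"), meta)
        truth.to_json(os.path.join(outdir, "ground_truth.json"))
        cfg.to_yaml(os.path.join(outdir, "config_echo.yaml"))
    return bundle
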