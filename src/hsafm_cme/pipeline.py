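"""End-to-end orchestration: simulate -> analyze -> evaluate.

``run_analyze`` chains detection, tracking, morphometry, identity
assignment, trace extraction, phase segmentation, closing-motion
classification and drift/diffusion estimation into a set of tidy
tables; ``run_evaluate`` scores them against the generator's ground
truth.  Closing-motion and identity decisions operate on *raw* measured
diameters (the aperture bands 150-400 nm, ~120 nm plateau, 80-120 nm
caveolae are as-measured AFM values); tip-corrected diameters are
reported alongside.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .detection import detect_movie
from .diffusion import (DriftEstimate, InsufficientDataError, ensemble_msd,
                        estimate_drift, fit_diffusion)
from .events import GroundTruth
from .generate import MovieBundle, generate_dataset
from .lifecycle import (ChannelAbsentError, IntensityTrace, NoSignalError,
                        detect_event_times, extract_trace, relative_timing,
                        segment_phases, timing_summary)
from .morphometry import (NoPitError, ProfileTruncationError, measure_diameter,
                          section_profile, tip_correct)
from .motions import (ClosingAnnotation, NotClassifiableError, classify_closing,
                      detect_swelling, motion_summary)
from .movio import FluorMovie, HeightMovie, read_movie
from .registration import RegistrationTransform, ScanGeometry, build_transform
from .render import optical_grid_shape
from .tracking import PitTrack, assign_identity, lifetime_and_rate, link_tracks

log = logging.getLogger("hsafm_cme")


def bundle_transform(cfg: SimulationConfig, pad_px: int = 6,
                     time_offset_s: float = 0.0) -> RegistrationTransform:
    """Registration transform matching the simulator's conventions.

    The common frame is centred on the scan area (the probe is parked at
    its centre), +y up; the fluorescence grid carries ``pad_px`` of
    padding around the scan rectangle.
    """
    width, height = cfg.scan_extent_nm
    corners = ((-width / 2e3, height / 2e3), (width / 2e3, height / 2e3),
               (width / 2e3, -height / 2e3), (-width / 2e3, -height / 2e3))
    opx = cfg.optical_pixel_nm
    origin = ((width / 2.0) / opx + pad_px - 0.5,
              (height / 2.0) / opx + pad_px - 0.5)
    geom = ScanGeometry(corners_um=corners, afm_pixel_nm=cfg.pixel_size_nm,
                        optical_pixel_nm=opx, probe_origin_px=origin)
    return build_transform(geom, time_offset_s)


# ---------------------------------------------------------------------------
# analysis
# ---------------------------------------------------------------------------

@dataclass
class AnalysisResult:
    tracks: list[PitTrack]
    track_table: pd.DataFrame
    morphometry: pd.DataFrame
    lifetimes: pd.DataFrame
    formation_rate_um2_min: float
    phases: pd.DataFrame
    timing: pd.DataFrame
    annotations: list[ClosingAnnotation]
    motion: Any = None                  # MotionSummary | None
    drift: DriftEstimate | None = None
    diffusion: pd.DataFrame | None = None
    traces: dict[int, dict[str, IntensityTrace]] = field(default_factory=dict)
    segmentations: dict[int, Any] = field(default_factory=dict)

    def write(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        self.track_table.to_csv(os.path.join(outdir, "tracks.csv"), index=False)
        self.morphometry.to_csv(os.path.join(outdir, "morphometry.csv"),
                                index=False)
        self.lifetimes.to_csv(os.path.join(outdir, "lifetimes.csv"), index=False)
        self.phases.to_csv(os.path.join(outdir, "phases.csv"), index=False)
        self.timing.to_csv(os.path.join(outdir, "timing.csv"), index=False)
        if self.diffusion is not None:
            self.diffusion.to_csv(os.path.join(outdir, "diffusion.csv"),
                                  index=False)
        if self.motion is not None:
            with open(os.path.join(outdir, "motion_summary.json"), "w") as fh:
                json.dump(self.motion.to_dict(), fh, indent=1, default=str)


def measure_track_diameters(height: HeightMovie, track: PitTrack,
                            tip_radius_nm: float,
                            depth_min_nm: float = 10.0,
                            section_angles: int = 1) -> pd.DataFrame:
    """Section-profile diameters for every open frame of a track."""
    px = height.pixel_size_nm
    rows = []
    for det in track.detections:
        half = max(1.5 * det.diameter_nm, 400.0)
        angles = [k * np.pi / section_angles for k in range(section_angles)]
        diams = []
        for ang in angles:
            try:
                prof = section_profile(height.frames[det.frame],
                                       (det.x_nm, det.y_nm), ang, half, px)
                diams.append(measure_diameter(prof, depth_min_nm))
            except (NoPitError, ProfileTruncationError, ValueError):
                continue
        raw = float(np.mean(diams)) if diams else np.nan
        if np.isnan(raw):
            raw_out = np.nan
            corr = np.nan
        else:
            raw_out = raw
            corr = (tip_correct(raw, tip_radius_nm)
                    if raw > 2 * tip_radius_nm else np.nan)
        rows.append({"event_id": track.track_id, "frame": det.frame,
                     "diameter_raw_nm": raw_out, "diameter_corrected_nm": corr,
                     "depth_nm": det.depth_nm,
                     "diameter_detection_nm": det.diameter_nm})
    return pd.DataFrame(rows)


def run_analyze(bundle: MovieBundle | None = None,
                height: HeightMovie | None = None,
                fluor: dict[str, FluorMovie] | None = None,
                cfg: SimulationConfig | None = None,
                drift_mode: str = "ensemble",
                section_angles: int = 1,
                outdir: str | None = None) -> AnalysisResult:
    """Run the full analysis chain on a bundle or on raw movies."""
    if bundle is not None:
        height = bundle.height
        fluor = bundle.fluor
        cfg = bundle.config
    if height is None or cfg is None:
        raise ValueError("either a bundle or (height, cfg) must be given")
    fluor = fluor or {}
    for ch, mv in fluor.items():
        if mv.n_frames != height.n_frames:
            raise ValueError(f"frame count mismatch: channel {ch} has "
                             f"{mv.n_frames} frames, AFM has {height.n_frames}")
    n_frames = height.n_frames
    dt = height.frame_interval_s
    transform = bundle_transform(cfg)

    detections = detect_movie(height.frames, height.pixel_size_nm,
                              artifact_log=height.artifact_log)
    tracks = link_tracks(detections)
    log.info("linked %d tracks from %d detections", len(tracks),
             sum(len(d) for d in detections))

    morpho_frames = []
    diam_maps: dict[int, dict[int, float]] = {}
    for tr in tracks:
        df = measure_track_diameters(height, tr, cfg.tip_radius_nm,
                                     section_angles=section_angles)
        morpho_frames.append(df)
        dm: dict[int, float] = {}
        for _, row in df.iterrows():
            d = row["diameter_raw_nm"]
            dm[int(row["frame"])] = float(d) if np.isfinite(d) \
                else float(row["diameter_detection_nm"])
        diam_maps[tr.track_id] = dm
    morphometry = (pd.concat(morpho_frames, ignore_index=True)
                   if morpho_frames else pd.DataFrame())

    for tr in tracks:
        if fluor:
            tr.identity = assign_identity(tr, fluor, transform)
        else:
            diam = float(np.nanmedian(list(diam_maps[tr.track_id].values())))
            tr.identity = ("caveola-like" if diam <= 120.0
                           else "CCP-like" if diam >= 150.0 else "unclassified")

    # traces, phases and timing
    traces: dict[int, dict[str, IntensityTrace]] = {}
    segmentations: dict[int, Any] = {}
    phase_rows, timing_events = [], []
    for tr in tracks:
        if len(tr.detections) < 2:
            continue
        t_inv, t_clo = detect_event_times(tr, n_frames, dt)
        per_ch: dict[str, IntensityTrace] = {}
        for ch, mv in fluor.items():
            trace = extract_trace(mv, tr, transform,
                                  psf_sigma_nm=cfg.psf_sigma_nm)
            per_ch[ch] = trace
            try:
                timing_events.append(
                    relative_timing(trace, t_inv, t_clo))
            except ChannelAbsentError:
                log.info("event %d: channel %s absent", tr.track_id, ch)
        traces[tr.track_id] = per_ch
        if "clathrin" in per_ch:
            try:
                seg = segment_phases(per_ch["clathrin"])
                segmentations[tr.track_id] = seg
                phase_rows.append({
                    "event_id": tr.track_id,
                    "growing_s": seg.growing_s, "stable_s": seg.stable_s,
                    "closing_s": seg.closing_s,
                    "stable_empty": seg.stable_empty,
                    "signal_start_frame": seg.signal_start + per_ch["clathrin"].start_frame,
                    "stable_start_frame": seg.stable_start + per_ch["clathrin"].start_frame,
                    "stable_end_frame": seg.stable_end + per_ch["clathrin"].start_frame,
                    "signal_end_frame": seg.signal_end + per_ch["clathrin"].start_frame})
            except (NoSignalError, ValueError):
                pass
    phases = pd.DataFrame(phase_rows)
    timing = timing_summary(timing_events)

    # closing motions (closed, CCP-flavoured tracks only)
    annotations: list[ClosingAnnotation] = []
    for tr in tracks:
        if tr.identity.startswith("caveola"):
            continue
        if tr.closure_frame(n_frames) is None:
            continue
        swelling = detect_swelling(height.frames, tr, height.pixel_size_nm)
        try:
            ann = classify_closing(
                tr, swelling, diam_maps[tr.track_id], n_frames, dt,
                clathrin_trace=traces.get(tr.track_id, {}).get("clathrin"),
                phase_seg=segmentations.get(tr.track_id))
        except NotClassifiableError:
            continue
        tr.motion_labels = ann.labels
        annotations.append(ann)

    lifetimes, rate = lifetime_and_rate(tracks, cfg.scan_area_um2,
                                        n_frames * dt, n_frames, dt)
    lt_map = {int(r["event_id"]): float(r["lifetime_s"])
              for _, r in lifetimes.iterrows() if np.isfinite(r["lifetime_s"])}
    motion = (motion_summary(annotations, lt_map, cfg.preset)
              if annotations else None)

    drift = None
    diffusion = None
    try:
        drift = estimate_drift(tracks, n_frames, method=drift_mode)
        rows = []
        for ident in sorted({t.identity for t in tracks}):
            sub = [t for t in tracks if t.identity == ident]
            try:
                est = fit_diffusion(ensemble_msd(sub, drift, dt),
                                    identity=ident)
                rows.append({"identity": ident, "d_cm2_s": est.d_cm2_s,
                             "se_cm2_s": est.se_cm2_s,
                             "n_tracks": len(sub)})
            except InsufficientDataError:
                continue
        diffusion = pd.DataFrame(rows)
    except InsufficientDataError:
        pass

    track_table = (pd.concat([t.to_frame(dt) for t in tracks],
                             ignore_index=True) if tracks else pd.DataFrame())
    result = AnalysisResult(tracks=tracks, track_table=track_table,
                            morphometry=morphometry, lifetimes=lifetimes,
                            formation_rate_um2_min=rate, phases=phases,
                            timing=timing, annotations=annotations,
                            motion=motion, drift=drift, diffusion=diffusion,
                            traces=traces, segmentations=segmentations)
    if outdir:
        result.write(outdir)
    return result


# ---------------------------------------------------------------------------
# evaluation against ground truth
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    n_truth: int
    n_tracks: int
    n_matched: int
    precision: float
    recall: float
    motion_metrics: dict[str, dict[str, float]]
    diameter_rmse_nm: float | None
    phase_mae_frames: float | None
    lifetime_mae_s: float | None

    def to_dict(self) -> dict[str, Any]:
        return {k: getattr(self, k) for k in
                ("n_truth", "n_tracks", "n_matched", "precision", "recall",
                 "motion_metrics", "diameter_rmse_nm", "phase_mae_frames",
                 "lifetime_mae_s")}


def match_tracks_to_truth(tracks: list[PitTrack], truth: GroundTruth,
                          max_dist_nm: float = 150.0) -> dict[int, int]:
    """Greedy matching of recovered tracks to truth events.

    Pairs are ranked by mean centroid distance over overlapping open
    frames (truth positions include the stage drift the tracker sees).
    Returns {track_id: event_id}.
    """
    pairs = []
    for tr in tracks:
        t_frames = tr.frames
        t_pos = tr.positions_nm
        for ev in truth.events:
            ev_open = set(int(f) for f in ev.open_frames)
            common = [k for k, f in enumerate(t_frames) if f in ev_open]
            if not common:
                continue
            ev_pos = np.array([ev.trajectory_nm[t_frames[k]]
                               + truth.cum_drift_nm[t_frames[k]]
                               for k in common])
            d = float(np.mean(np.linalg.norm(t_pos[common] - ev_pos, axis=1)))
            if d <= max_dist_nm:
                pairs.append((d, tr.track_id, ev.event_id))
    matched: dict[int, int] = {}
    used_ev: set[int] = set()
    for d, tid, eid in sorted(pairs):
        if tid in matched or eid in used_ev:
            continue
        matched[tid] = eid
        used_ev.add(eid)
    return matched


def run_evaluate(result: AnalysisResult, truth: GroundTruth,
                 cfg: SimulationConfig) -> EvaluationReport:
    """Score an analysis of a simulated bundle against its ground truth."""
    tracks = result.tracks
    matched = match_tracks_to_truth(tracks, truth)
    n_truth = len(truth.events)
    n_tracks = len(tracks)
    n_matched = len(matched)
    precision = n_matched / n_tracks if n_tracks else 0.0
    recall = n_matched / n_truth if n_truth else 0.0

    # closing-motion confusion per label
    ann_by_track = {a.event_id: a for a in result.annotations}
    ev_by_id = {ev.event_id: ev for ev in truth.events}
    motion_metrics: dict[str, dict[str, float]] = {}
    for label in ("capping", "two_step", "reopen", "plain"):
        tp = fp = fn = 0
        for tid, eid in matched.items():
            ann = ann_by_track.get(tid)
            ev = ev_by_id[eid]
            if ann is None or ev.final_closure_frame is None:
                continue
            pred = label in ann.labels
            true = label in ev.motion_labels
            tp += pred and true
            fp += pred and not true
            fn += true and not pred
        prec = tp / (tp + fp) if tp + fp else float("nan")
        rec = tp / (tp + fn) if tp + fn else float("nan")
        motion_metrics[label] = {"tp": tp, "fp": fp, "fn": fn,
                                 "precision": prec, "recall": rec}

    # diameter RMSE over matched open frames
    sq_errs = []
    morpho = result.morphometry
    if len(morpho):
        by_track = {tid: g.set_index("frame")["diameter_raw_nm"]
                    for tid, g in morpho.groupby("event_id")}
        for tid, eid in matched.items():
            ev = ev_by_id[eid]
            series = by_track.get(tid)
            if series is None:
                continue
            for f, d in series.items():
                if np.isfinite(d) and ev.is_open(int(f)):
                    sq_errs.append((d - ev.aperture_nm[int(f)]) ** 2)
    diameter_rmse = float(np.sqrt(np.mean(sq_errs))) if sq_errs else None

    # phase boundary MAE (frames), clathrin
    errs = []
    for tid, eid in matched.items():
        ev = ev_by_id[eid]
        seg = result.segmentations.get(tid)
        if seg is None or not ev.phase_truth_frames:
            continue
        tr = result.traces[tid]["clathrin"]
        truth_b = ev.phase_truth_frames.get("clathrin")
        if truth_b is None:
            continue
        got = (seg.signal_start + tr.start_frame,
               seg.stable_start + tr.start_frame,
               seg.stable_end + tr.start_frame,
               seg.signal_end + tr.start_frame)
        errs.extend(abs(g - t) for g, t in zip(got, truth_b))
    phase_mae = float(np.mean(errs)) if errs else None

    # lifetime MAE
    lt_errs = []
    lt_map = {int(r["event_id"]): r["lifetime_s"]
              for _, r in result.lifetimes.iterrows()}
    for tid, eid in matched.items():
        ev = ev_by_id[eid]
        true_lt = ev.lifetime_s(cfg.frame_interval_s)
        got_lt = lt_map.get(tid)
        if true_lt is not None and got_lt is not None and np.isfinite(got_lt):
            lt_errs.append(abs(got_lt - true_lt))
    lifetime_mae = float(np.mean(lt_errs)) if lt_errs else None

    return EvaluationReport(n_truth=n_truth, n_tracks=n_tracks,
                            n_matched=n_matched, precision=precision,
                            recall=recall, motion_metrics=motion_metrics,
                            diameter_rmse_nm=diameter_rmse,
                            phase_mae_frames=phase_mae,
                            lifetime_mae_s=lifetime_mae)


# ---------------------------------------------------------------------------
# disk-level entry points
# ---------------------------------------------------------------------------

def run_simulate(cfg: SimulationConfig, outdir: str) -> MovieBundle:
    """Simulate a bundle and write stacks, truth and config echo."""
    return generate_dataset(cfg, outdir=outdir)


def load_bundle(outdir: str) -> MovieBundle:
    """Re-load a bundle previously written by :func:`run_simulate`."""
    cfg = SimulationConfig.from_yaml(os.path.join(outdir, "config_echo.yaml"))
    height = read_movie(os.path.join(outdir, "afm_height.tif"))
    fluor = {}
    for ch in cfg.channels:
        path = os.path.join(outdir, f"fluor_{ch}.tif")
        if os.path.exists(path):
            fluor[ch] = read_movie(path)
    truth = GroundTruth.from_json(os.path.join(outdir, "ground_truth.json"))
    return MovieBundle(height=height, fluor=fluor, truth=truth, config=cfg)
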