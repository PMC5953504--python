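"""Classification of pit closing motions: capping, two-step, re-opening.

Capping: a membrane swelling (~380 nm wide, ~40 nm high) rises adjacent
to the pit around closure and covers its former position.  Two-step:
the aperture first shrinks to a small (~120 nm) plateau before final
disappearance.  Re-opening: a closed pit reappears within ~113 nm of
its closure position after a 10-70 s gap, retaining part of its
clathrin signal in between.  Labels are not mutually exclusive except
capping vs re-opening; events with none of the motions are "plain".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .detection import local_baseline
from .lifecycle import IntensityTrace, PhaseSegmentation
from .morphometry import (NoPeakError, NoPitError, ProfileTruncationError,
                          measure_bump_width, measure_height, section_profile)
from .tracking import PitTrack


class NotClassifiableError(ValueError):
    """Track never closes within the movie."""


@dataclass
class SwellingRecord:
    frame: int                      # frame of maximum measured height
    center_nm: tuple[float, float]
    diameter_nm: float
    height_nm: float
    direction: tuple[float, float]  # approach direction from the pit centre
    covered: bool


@dataclass
class ClosingAnnotation:
    event_id: int
    labels: frozenset[str]
    closing_duration_s: float
    swelling: SwellingRecord | None = None
    plateau_frames: tuple[int, int] | None = None     # [start, end)
    plateau_diameter_nm: float | None = None
    large_aperture_s: float | None = None
    small_aperture_s: float | None = None
    reopen_gap_s: float | None = None
    reopen_displacement_nm: float | None = None
    reopen_retention: float | None = None


def detect_swelling(height_frames: np.ndarray, track: PitTrack,
                    pixel_size_nm: float, window_frames: int = 3,
                    min_height_nm: float = 20.0, min_width_nm: float = 150.0,
                    search_factor: float = 1.5,
                    profile_half_length_nm: float = 600.0,
                    baseline_window_nm: float = 1500.0) -> SwellingRecord | None:
    """Find a covering membrane swelling around a track's closure.

    Searches frames within ``window_frames`` of closure, within
    ``search_factor`` x the last pit diameter of the pit centre, for a
    positive structure at least ``min_height_nm`` high and
    ``min_width_nm`` wide; "covering" requires its elevation to reach
    the former pit position at or after closure.
    """
    n_frames = height_frames.shape[0]
    closure = track.closure_frame(n_frames)
    if closure is None:
        return None
    last_pos = track.positions_nm[-1]
    last_diam = float(np.median(track.diameters_nm[-3:]))
    # floor at a typical pit size: the pit keeps diffusing between its
    # last detection and the swelling peak, so the search must be generous
    search_nm = search_factor * max(last_diam, 250.0)

    f0 = max(0, closure - window_frames)
    f1 = min(n_frames - 1, closure - 1 + window_frames)
    best: SwellingRecord | None = None
    covered = False
    for f in range(f0, f1 + 1):
        grid = height_frames[f].astype(float)
        # window much wider than the swelling so it cannot lift its own
        # baseline (median filters suppress structures filling >50%)
        baseline = local_baseline(grid, pixel_size_nm,
                                  window_nm=baseline_window_nm)
        elev = grid - baseline
        rows, cols = grid.shape
        xs = (np.arange(cols) + 0.5) * pixel_size_nm
        ys = (np.arange(rows) + 0.5) * pixel_size_nm
        rr = np.hypot(xs[None, :] - last_pos[0], ys[:, None] - last_pos[1])
        local = np.where(rr <= search_nm, elev, -np.inf)
        r_peak, c_peak = np.unravel_index(np.argmax(local), local.shape)
        if local[r_peak, c_peak] < min_height_nm:
            continue
        center = (float(xs[c_peak]), float(ys[r_peak]))
        try:
            prof = section_profile(grid, center, 0.0, profile_half_length_nm,
                                   pixel_size_nm)
            height = measure_height(prof, min_height_nm / 2.0)
            width = measure_bump_width(prof, min_height_nm / 2.0)
        except (NoPeakError, NoPitError, ProfileTruncationError, ValueError):
            continue
        if height < min_height_nm or width < min_width_nm:
            continue
        if f >= closure:
            # covering: the swelling footprint overlaps the former pit centre
            if np.hypot(center[0] - last_pos[0],
                        center[1] - last_pos[1]) <= width / 2.0:
                covered = True
        if best is None or height > best.height_nm:
            vec = np.array(center) - last_pos
            norm = np.linalg.norm(vec)
            direction = tuple(vec / norm) if norm > 0 else (0.0, 0.0)
            best = SwellingRecord(frame=f, center_nm=center,
                                  diameter_nm=width, height_nm=height,
                                  direction=direction, covered=covered)
    if best is None:
        return None
    best.covered = covered
    return best if covered else None


def _reopen_record(track: PitTrack, dt_s: float,
                   max_displacement_nm: float = 140.0,
                   max_gap_frames: int = 7
                   ) -> tuple[float, float] | None:
    """(gap duration s, displacement nm) of the track's closed gap, if any."""
    frames = track.frames
    for g0, g1 in track.gaps:
        gap_frames = g1 - g0
        if not 1 <= gap_frames <= max_gap_frames:
            continue
        i_before = int(np.searchsorted(frames, g0) - 1)
        i_after = int(np.searchsorted(frames, g1))
        if i_before < 0 or i_after >= len(frames):
            continue
        disp = float(np.linalg.norm(track.positions_nm[i_after]
                                    - track.positions_nm[i_before]))
        if disp <= max_displacement_nm:
            return gap_frames * dt_s, disp
    return None


def classify_closing(track: PitTrack, swelling: SwellingRecord | None,
                     diameters_nm: Mapping[int, float], n_frames: int,
                     dt_s: float, clathrin_trace: IntensityTrace | None = None,
                     phase_seg: PhaseSegmentation | None = None,
                     plateau_band_nm: tuple[float, float] = (60.0, 150.0),
                     large_min_nm: float = 140.0,
                     step_min_nm: float = 25.0) -> ClosingAnnotation:
    """Assign closing-motion labels to a closed track.

    ``diameters_nm`` maps open frames to measured (tip-corrected)
    aperture diameters; detection equivalent diameters are an acceptable
    fallback.
    """
    closure = track.closure_frame(n_frames)
    if closure is None:
        raise NotClassifiableError("track does not close within the movie")
    labels: set[str] = set()

    if swelling is not None and swelling.covered:
        labels.add("capping")

    # two-step: small-aperture plateau immediately before final closure,
    # preceded by at least two large-aperture frames
    open_frames = [f for f in track.frames if f in diameters_nm]
    plateau_frames = None
    plateau_diam = None
    large_s = small_s = None
    if open_frames:
        lo, hi = plateau_band_nm
        run: list[int] = []
        for f in reversed(open_frames):
            if lo <= diameters_nm[f] < hi:
                run.append(f)
            else:
                break
        run.reverse()
        if run:
            large = [diameters_nm[f] for f in open_frames if f < run[0]
                     and diameters_nm[f] >= large_min_nm]
            run_med = float(np.median([diameters_nm[f] for f in run]))
            # a genuine two-step shows a clear aperture *step*, not just a
            # measurement dip below the band edge
            if len(large) >= 2 and float(np.median(large)) - run_med >= step_min_nm:
                labels.add("two_step")
                plateau_frames = (run[0], run[-1] + 1)
                plateau_diam = float(np.median([diameters_nm[f] for f in run]))
                small_s = (plateau_frames[1] - plateau_frames[0]) * dt_s
                large_s = (run[0] - track.first_frame) * dt_s

    reopen = _reopen_record(track, dt_s)
    if reopen is not None:
        labels.add("reopen")
    retention = None
    if reopen is not None and clathrin_trace is not None:
        g0, g1 = track.gaps[0]
        # the coat keeps disassembling through the closed state, so the
        # retained minimum sits at the re-opening frame: include it
        lo_i = g0 - clathrin_trace.start_frame
        hi_i = g1 - clathrin_trace.start_frame + 1
        v = clathrin_trace.values
        if 0 <= lo_i and hi_i <= len(v) and v.max() > 0:
            retention = float(v[lo_i:hi_i].min() / v.max())

    if not labels:
        labels.add("plain")

    # closing duration: stable-phase end (or diameter-decline onset) to closure
    if phase_seg is not None and not phase_seg.stable_empty:
        t_end_stable = phase_seg.stable_end * dt_s
        closing_s = max(dt_s, closure * dt_s - t_end_stable)
    elif open_frames:
        diams = np.array([diameters_nm[f] for f in open_frames])
        ref = float(np.median(diams)) if len(diams) > 2 else diams.max()
        decline = [f for f, d in zip(open_frames, diams) if d < 0.9 * ref]
        onset = decline[0] if decline else open_frames[-1]
        closing_s = max(dt_s, (closure - onset) * dt_s)
    else:
        closing_s = dt_s

    return ClosingAnnotation(
        event_id=track.track_id, labels=frozenset(labels),
        closing_duration_s=closing_s, swelling=swelling,
        plateau_frames=plateau_frames, plateau_diameter_nm=plateau_diam,
        large_aperture_s=large_s, small_aperture_s=small_s,
        reopen_gap_s=reopen[0] if reopen else None,
        reopen_displacement_nm=reopen[1] if reopen else None,
        reopen_retention=retention)


@dataclass
class MotionSummary:
    condition: str
    n_events: int
    counts: dict[str, int]
    percentages: dict[str, float]
    crosstab: pd.DataFrame                       # capping x reopen
    lifetimes_by_label: dict[str, list[float]]
    aperture_durations: pd.DataFrame             # large/small per two-step event

    def to_dict(self) -> dict[str, Any]:
        return {"condition": self.condition, "n_events": self.n_events,
                "counts": self.counts, "percentages": self.percentages,
                "crosstab": self.crosstab.to_dict(),
                "lifetimes_by_label": self.lifetimes_by_label,
                "aperture_durations": self.aperture_durations.to_dict("records")}


def motion_summary(annotations: list[ClosingAnnotation],
                   lifetimes_s: Mapping[int, float] | None = None,
                   condition: str = "untreated") -> MotionSummary:
    """Population frequencies, capping x re-open cross-tab and lifetime
    distributions per closing-motion label."""
    if not annotations:
        raise ValueError("no annotations to summarise")
    n = len(annotations)
    all_labels = ("capping", "two_step", "reopen", "plain")
    counts = {lab: sum(1 for a in annotations if lab in a.labels)
              for lab in all_labels}
    pct = {lab: 100.0 * c / n for lab, c in counts.items()}

    ct = np.zeros((2, 2), dtype=int)
    for a in annotations:
        ct[int("capping" in a.labels), int("reopen" in a.labels)] += 1
    crosstab = pd.DataFrame(ct, index=["no_capping", "capping"],
                            columns=["no_reopen", "reopen"])

    lifetimes_by_label: dict[str, list[float]] = {lab: [] for lab in all_labels}
    if lifetimes_s:
        for a in annotations:
            lt = lifetimes_s.get(a.event_id)
            if lt is None:
                continue
            for lab in a.labels:
                lifetimes_by_label[lab].append(float(lt))

    rows = [{"event_id": a.event_id, "large_aperture_s": a.large_aperture_s,
             "small_aperture_s": a.small_aperture_s}
            for a in annotations if "two_step" in a.labels]
    durations = pd.DataFrame(rows, columns=["event_id", "large_aperture_s",
                                            "small_aperture_s"])
    return MotionSummary(condition=condition, n_events=n, counts=counts,
                         percentages=pct, crosstab=crosstab,
                         lifetimes_by_label=lifetimes_by_label,
                         aperture_durations=durations)
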