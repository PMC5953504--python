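"""Linking pit detections into per-event tracks.

Frame-to-frame greedy nearest-neighbour linking within ``r_link``
(adequate at the sparse pit densities of these movies), followed by a
gap-closing pass that can bridge up to ``g_max`` missing frames within
``r_reopen`` — the mechanism by which re-opening events (closed for
10-70 s, re-appearing within ~113 nm) stay one track.  Identity (CCP vs
caveola) is assigned by marker colocalization with a size-prior
fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detection import PitDetection
from .movio import FluorMovie
from .registration import RegistrationTransform, spot_centroid


@dataclass
class PitTrack:
    track_id: int
    detections: list[PitDetection]
    gaps: list[tuple[int, int]] = field(default_factory=list)  # [start, end)
    identity: str = "unclassified"
    motion_labels: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.detections = sorted(self.detections, key=lambda d: d.frame)

    @property
    def frames(self) -> np.ndarray:
        return np.array([d.frame for d in self.detections], dtype=int)

    @property
    def positions_nm(self) -> np.ndarray:
        return np.array([[d.x_nm, d.y_nm] for d in self.detections])

    @property
    def diameters_nm(self) -> np.ndarray:
        return np.array([d.diameter_nm for d in self.detections])

    @property
    def first_frame(self) -> int:
        return self.detections[0].frame

    @property
    def last_frame(self) -> int:
        return self.detections[-1].frame

    def has_confirmed_run(self, min_frames: int = 2) -> bool:
        frames = self.frames
        run = best = 1
        for a, b in zip(frames[:-1], frames[1:]):
            run = run + 1 if b == a + 1 else 1
            best = max(best, run)
        return best >= min_frames

    def is_censored(self, n_frames: int) -> bool:
        return self.first_frame == 0 or self.last_frame >= n_frames - 1

    def closure_frame(self, n_frames: int) -> int | None:
        """First frame with no detection after the final open frame."""
        if self.last_frame >= n_frames - 1:
            return None
        return self.last_frame + 1

    def lifetime_s(self, n_frames: int, dt_s: float) -> float | None:
        closure = self.closure_frame(n_frames)
        if closure is None:
            return None
        return (closure - self.first_frame) * dt_s

    def mean_position(self) -> np.ndarray:
        return self.positions_nm.mean(axis=0)

    def to_frame(self, dt_s: float) -> pd.DataFrame:
        gap_frames = {f for g0, g1 in self.gaps for f in range(g0, g1)}
        rows = [{"event_id": self.track_id, "frame": d.frame,
                 "t_s": d.frame * dt_s, "x_nm": d.x_nm, "y_nm": d.y_nm,
                 "depth_nm": d.depth_nm, "diameter_nm": d.diameter_nm,
                 "state": "open", "identity": self.identity}
                for d in self.detections]
        rows += [{"event_id": self.track_id, "frame": f, "t_s": f * dt_s,
                  "x_nm": np.nan, "y_nm": np.nan, "depth_nm": np.nan,
                  "diameter_nm": np.nan, "state": "closed_gap",
                  "identity": self.identity} for f in sorted(gap_frames)]
        return pd.DataFrame(rows).sort_values("frame").reset_index(drop=True)


def _greedy_pairs(cost: np.ndarray, max_cost: float) -> list[tuple[int, int]]:
    """Greedy ascending-cost assignment; each row/col used at most once."""
    pairs: list[tuple[int, int]] = []
    if cost.size == 0:
        return pairs
    used_r: set[int] = set()
    used_c: set[int] = set()
    order = np.argsort(cost, axis=None)
    for flat in order:
        r, c = np.unravel_index(flat, cost.shape)
        if cost[r, c] > max_cost:
            break
        if r in used_r or c in used_c:
            continue
        pairs.append((int(r), int(c)))
        used_r.add(int(r))
        used_c.add(int(c))
    return pairs


def link_tracks(detections_by_frame: list[list[PitDetection]],
                r_link_nm: float = 250.0, g_max_frames: int = 7,
                r_reopen_nm: float = 140.0, r_rescue_nm: float = 350.0,
                min_confirm_frames: int = 2) -> list[PitTrack]:
    """Link detections into tracks with gap closing.

    Each detection is claimed by at most one track; tracks without a run
    of ``min_confirm_frames`` consecutive detections are discarded as
    single-frame blips.  The gap-closing pass also reconsiders zero-gap
    splits (a track end abutting a track start in the next frame) within
    ``r_rescue_nm``, which recovers the rare Brownian step beyond
    ``r_link_nm``.
    """
    tracks: list[list[PitDetection]] = []
    active: list[int] = []      # indices into tracks with a detection last frame
    for frame, dets in enumerate(detections_by_frame):
        if not dets:
            active = []
            continue
        new_active: list[int] = []
        if active:
            last_pos = np.array([[tracks[i][-1].x_nm, tracks[i][-1].y_nm]
                                 for i in active])
            cur_pos = np.array([[d.x_nm, d.y_nm] for d in dets])
            cost = np.linalg.norm(last_pos[:, None, :] - cur_pos[None, :, :],
                                  axis=2)
            pairs = _greedy_pairs(cost, r_link_nm)
            matched = {c for _, c in pairs}
            for r, c in pairs:
                tracks[active[r]].append(dets[c])
                new_active.append(active[r])
        else:
            matched = set()
        for c, d in enumerate(dets):
            if c not in matched:
                tracks.append([d])
                new_active.append(len(tracks) - 1)
        active = new_active

    # gap closing: bridge track ends to later track starts
    order = sorted(range(len(tracks)), key=lambda i: tracks[i][0].frame)
    merged_into: dict[int, int] = {}
    gaps: dict[int, list[tuple[int, int]]] = {i: [] for i in range(len(tracks))}

    def root(i: int) -> int:
        while i in merged_into:
            i = merged_into[i]
        return i

    candidates: list[tuple[float, int, int]] = []
    for i in order:
        for j in order:
            if i == j:
                continue
            end_f = tracks[i][-1].frame
            start_f = tracks[j][0].frame
            gap = start_f - end_f - 1
            if not 0 <= gap <= g_max_frames:
                continue
            d = float(np.hypot(tracks[i][-1].x_nm - tracks[j][0].x_nm,
                               tracks[i][-1].y_nm - tracks[j][0].y_nm))
            if d <= (r_rescue_nm if gap == 0 else r_reopen_nm):
                candidates.append((d, i, j))
    used_ends: set[int] = set()
    used_starts: set[int] = set()
    for d, i, j in sorted(candidates):
        ri = root(i)
        if ri in used_ends or j in used_starts or ri == root(j):
            continue
        if tracks[j][0].frame <= tracks[ri][-1].frame:
            continue
        gap_iv = (tracks[ri][-1].frame + 1, tracks[j][0].frame)
        tracks[ri].extend(tracks[j])
        if gap_iv[1] > gap_iv[0]:          # zero-gap rescue has no gap
            gaps[ri].append(gap_iv)
        gaps[ri].extend(gaps[j])
        merged_into[j] = ri
        used_ends.add(ri)
        used_starts.add(j)

    out: list[PitTrack] = []
    tid = 0
    for i in range(len(tracks)):
        if i in merged_into:
            continue
        tr = PitTrack(track_id=tid, detections=tracks[i],
                      gaps=sorted(gaps[i]))
        if tr.has_confirmed_run(min_confirm_frames):
            tr.track_id = tid
            out.append(tr)
            tid += 1
    return out


def assign_identity(track: PitTrack, fluor: dict[str, FluorMovie],
                    transform: RegistrationTransform,
                    r_coloc_nm: float = 150.0, window_px: int = 5,
                    tip_radius_nm: float = 0.0) -> str:
    """Identity by marker colocalization, falling back to a size prior."""
    marker_identity = {"clathrin": "CCP", "caveolin": "caveola"}
    votes: dict[str, tuple[float, float]] = {}
    for ch, movie in fluor.items():
        if ch not in marker_identity:
            continue
        hits, intensity = 0, 0.0
        for det in track.detections:
            xy_nm = transform.scanlocal_to_nm(np.array([det.x_nm, det.y_nm]))
            colrow = transform.nm_to_optical_px(xy_nm)
            res = spot_centroid(movie.frames[det.frame], tuple(colrow), window_px)
            if res is None:
                continue
            spot_nm = transform.optical_px_to_nm(np.array(res[0]))
            if np.hypot(*(spot_nm - xy_nm)) <= r_coloc_nm:
                hits += 1
                intensity += res[1]
        frac = hits / len(track.detections)
        if frac >= 0.5:
            votes[marker_identity[ch]] = (frac, intensity)
    if votes:
        # ties on the frame fraction are broken by mean intensity
        return max(votes.items(), key=lambda kv: kv[1])[0]

    diam = float(np.median(track.diameters_nm))
    if tip_radius_nm > 0 and diam > 2 * tip_radius_nm:
        diam -= 2 * tip_radius_nm
    if diam <= 120.0:
        return "caveola-like"
    if diam >= 150.0:
        return "CCP-like"
    return "unclassified"


def lifetime_and_rate(tracks: list[PitTrack], scan_area_um2: float,
                      duration_s: float, n_frames: int,
                      dt_s: float) -> tuple[pd.DataFrame, float]:
    """Per-track lifetimes and the formation frequency.

    Tracks alive at either movie edge are censored and excluded from the
    mean lifetime; the formation frequency counts tracks born after the
    first frame, in events um^-2 min^-1.
    """
    if duration_s <= 0 or scan_area_um2 <= 0:
        raise ValueError("movie duration and area must be > 0")
    rows = []
    for tr in tracks:
        censored = tr.is_censored(n_frames)
        rows.append({"event_id": tr.track_id, "identity": tr.identity,
                     "first_frame": tr.first_frame, "last_frame": tr.last_frame,
                     "censored": censored,
                     "lifetime_s": tr.lifetime_s(n_frames, dt_s)
                     if not censored else np.nan})
    table = pd.DataFrame(rows)
    n_new = int((table["first_frame"] > 0).sum()) if len(table) else 0
    rate = n_new / (scan_area_um2 * duration_s / 60.0)
    return table, rate
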