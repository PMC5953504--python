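"""Sampling of endocytic event specifications.

Each event is a clathrin-coated pit (CCP) or a caveola with a full
per-frame script: intrinsic Brownian trajectory, aperture time course,
closing-motion labels (capping / two-step / re-opening), swelling
geometry for capping events, and per-channel fluorescence timing
anchors.  The sampled parameters double as ground truth for evaluating
the analysis chain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np

from .config import SimulationConfig
from .trajectory import sample_trajectory

CCP = "CCP"
CAVEOLA = "caveola"


@dataclass
class SwellingSpec:
    """Geometry and schedule of the membrane swelling of a capping event."""

    diameter_nm: float
    height_nm: float
    direction: tuple[float, float]      # unit vector of approach
    onset_frame: int
    peak_frame: int
    end_frame: int                      # exclusive

    def height_factor(self, frame: int) -> float:
        """Relative height of the swelling at a frame (1 at the peak)."""
        if frame < self.onset_frame or frame >= self.end_frame:
            return 0.0
        if frame <= self.peak_frame:
            rise = self.peak_frame - self.onset_frame
            return 1.0 if rise == 0 else 0.3 + 0.7 * (frame - self.onset_frame) / rise
        fall = self.end_frame - self.peak_frame
        return max(0.0, 1.0 - (frame - self.peak_frame) / fall)

    def center_offset(self, frame: int, pit_radius_nm: float) -> tuple[float, float]:
        """Offset of the swelling centre from the pit centre (nm).

        The swelling grows adjacent to the pit (from ``direction``) while
        the pit is still open, then rapidly covers it: from the peak frame
        onward it is centred on the former pit position.
        """
        if frame >= self.peak_frame:
            return (0.0, 0.0)
        d0 = 0.9 * (pit_radius_nm + self.diameter_nm / 2.0)
        return (d0 * self.direction[0], d0 * self.direction[1])


@dataclass
class EventSpec:
    event_id: int
    identity: str
    birth_frame: int
    invagination_frame: int
    closure_frame: int | None           # first closed frame (None: open at end)
    final_closure_frame: int | None     # after any re-opening
    motion_labels: frozenset[str]
    max_aperture_nm: float
    aperture_nm: np.ndarray             # per frame; NaN while closed/absent
    trajectory_nm: np.ndarray           # (n_frames, 2) intrinsic positions
    plateau_diameter_nm: float | None = None
    plateau_frames: tuple[int, int] | None = None      # [start, end)
    reopen_gap_frames: tuple[int, int] | None = None   # closed interval [start, end)
    reopen_displacement_nm: float | None = None
    reopen_retention: float | None = None
    swelling: SwellingSpec | None = None
    channel_times_s: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    phase_truth_frames: dict[str, tuple[int, int, int, int]] | None = None

    @property
    def open_frames(self) -> np.ndarray:
        return np.flatnonzero(np.isfinite(self.aperture_nm))

    def is_open(self, frame: int) -> bool:
        return bool(np.isfinite(self.aperture_nm[frame]))

    def lifetime_s(self, dt_s: float) -> float | None:
        if self.final_closure_frame is None:
            return None
        return (self.final_closure_frame - self.birth_frame) * dt_s


@dataclass
class GroundTruth:
    events: list[EventSpec]
    cum_drift_nm: np.ndarray            # (n_frames, 2)
    artifact_log: list[dict[str, Any]]
    time_lag_s: float = 0.0

    def to_json(self, path: str) -> None:
        def enc(o: Any) -> Any:
            if isinstance(o, np.ndarray):
                return np.where(np.isfinite(o), o, None).tolist() \
                    if o.dtype.kind == "f" else o.tolist()
            if isinstance(o, frozenset):
                return sorted(o)
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(f"not JSON-serialisable: {type(o)}")

        payload = {
            "events": [asdict(ev) for ev in self.events],
            "cum_drift_nm": self.cum_drift_nm,
            "artifact_log": self.artifact_log,
            "time_lag_s": self.time_lag_s,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, default=enc)

    @classmethod
    def from_json(cls, path: str) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        events = []
        for d in payload["events"]:
            d = dict(d)
            ap = np.array([np.nan if v is None else v for v in d["aperture_nm"]],
                          dtype=float)
            d["aperture_nm"] = ap
            d["trajectory_nm"] = np.asarray(d["trajectory_nm"], dtype=float)
            d["motion_labels"] = frozenset(d["motion_labels"])
            if d.get("swelling") is not None:
                sw = dict(d["swelling"])
                sw["direction"] = tuple(sw["direction"])
                d["swelling"] = SwellingSpec(**sw)
            for key in ("plateau_frames", "reopen_gap_frames"):
                if d.get(key) is not None:
                    d[key] = tuple(d[key])
            d["channel_times_s"] = {k: tuple(v)
                                    for k, v in d["channel_times_s"].items()}
            if d.get("phase_truth_frames") is not None:
                d["phase_truth_frames"] = {k: tuple(v)
                                           for k, v in d["phase_truth_frames"].items()}
            events.append(EventSpec(**d))
        return cls(events=events,
                   cum_drift_nm=np.asarray(payload["cum_drift_nm"], dtype=float),
                   artifact_log=payload["artifact_log"],
                   time_lag_s=payload["time_lag_s"])


# ---------------------------------------------------------------------------
# distribution helpers
# ---------------------------------------------------------------------------

from functools import lru_cache


@lru_cache(maxsize=32)
def _calibrated_lognormal(mean_above_lo: float, sd: float,
                          cap: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal whose truncation to [0, cap] has the
    requested mean and SD (closed-form truncated moments)."""
    from scipy import optimize
    from scipy.stats import norm

    def moments(params):
        mu, sigma = params
        if sigma <= 0:
            return [1e6, 1e6]
        z = (np.log(cap) - mu) / sigma
        p0 = norm.cdf(z)
        if p0 <= 1e-12:
            return [1e6, 1e6]
        m1 = np.exp(mu + sigma ** 2 / 2) * norm.cdf(z - sigma) / p0
        m2 = np.exp(2 * mu + 2 * sigma ** 2) * norm.cdf(z - 2 * sigma) / p0
        var = m2 - m1 ** 2
        return [m1 - mean_above_lo, np.sqrt(max(var, 0.0)) - sd]

    s2 = np.log1p((sd / mean_above_lo) ** 2)
    start = [np.log(mean_above_lo) - s2 / 2.0, np.sqrt(s2)]
    sol = optimize.root(moments, x0=start)
    if sol.success and abs(moments(sol.x)[0]) < 0.5 and abs(moments(sol.x)[1]) < 0.5:
        return float(sol.x[0]), float(sol.x[1])
    return float(start[0]), float(start[1])      # infeasible target: best effort


def sample_ccp_lifetime_s(rng: np.random.Generator,
                          mean_s: float = 81.0, sd_s: float = 55.0,
                          lo_s: float = 40.0, hi_s: float = 330.0) -> float:
    """Draw a CCP lifetime.

    A shifted lognormal is used — ``lo + LogNormal`` rejected above
    ``hi`` — with the lognormal parameters calibrated so the *truncated*
    draw reproduces the requested mean and SD.  (A normal truncated to
    [lo, hi] cannot reproduce mean 81 s with SD 55 s, since ``lo`` sits
    only 0.75 SD below the mean; and an uncalibrated lognormal loses a
    third of its SD to the upper truncation.)
    """
    m = mean_s - lo_s
    if m <= 0:
        raise ValueError("lifetime mean must exceed the lower bound")
    mu, sigma = _calibrated_lognormal(round(m, 6), round(sd_s, 6),
                                      round(hi_s - lo_s, 6))
    for _ in range(1000):
        x = lo_s + rng.lognormal(mu, sigma)
        if x <= hi_s:
            return float(x)
    return float(hi_s)


def _unit_vector(rng: np.random.Generator) -> tuple[float, float]:
    phi = rng.uniform(0.0, 2.0 * np.pi)
    return (float(np.cos(phi)), float(np.sin(phi)))


def sample_motion_labels(rng: np.random.Generator, mixture) -> frozenset[str]:
    """Draw closing-motion labels from the configured marginals.

    Capping and re-opening are mutually exclusive (the data show an
    inverse relation); two-step may co-occur with either.
    """
    labels: set[str] = set()
    u = rng.uniform()
    if u < mixture.capping:
        labels.add("capping")
    elif u < mixture.capping + mixture.reopen:
        labels.add("reopen")
    if rng.uniform() < mixture.two_step:
        labels.add("two_step")
    if not labels:
        labels.add("plain")
    return frozenset(labels)


def _channel_times(rng: np.random.Generator, cfg: SimulationConfig,
                   t_inv_s: float, t_clo_s: float | None,
                   t_end_s: float) -> dict[str, tuple[float, float, float]]:
    """Draw absolute (appearance, peak, disappearance) times per channel."""
    dt = cfg.frame_interval_s
    out: dict[str, tuple[float, float, float]] = {}
    t_clo = t_clo_s if t_clo_s is not None else t_end_s
    for ch in cfg.channels:
        tm = cfg.timing[ch]
        anchor = t_inv_s if tm.appearance_anchor == "invagination" else t_clo
        app = anchor - max(0.0, rng.normal(*tm.appearance_before_s))
        app = max(0.0, app)
        disapp = t_clo + max(dt, rng.normal(*tm.disappearance_after_closure_s))
        peak = t_clo + rng.normal(*tm.peak_after_closure_s)
        peak = float(np.clip(peak, app + 2 * dt, disapp - 0.5 * dt))
        out[ch] = (float(app), float(peak), float(disapp))
    return out


# ---------------------------------------------------------------------------
# event sampling
# ---------------------------------------------------------------------------

def _reflect(positions: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Reflect a trajectory into the box [lo, hi] (per axis)."""
    span = hi - lo
    if np.any(span <= 0):
        return np.clip(positions, np.minimum(lo, hi), np.maximum(lo, hi))
    p = np.mod(positions - lo, 2 * span)
    p = np.where(p > span, 2 * span - p, p)
    return lo + p


def sample_events(cfg: SimulationConfig,
                  rng: np.random.Generator) -> list[EventSpec]:
    """Draw ``cfg.n_events`` event scripts for one movie."""
    dt = cfg.frame_interval_s
    n = cfg.n_frames
    width, height = cfg.scan_extent_nm
    geo, kin = cfg.geometry, cfg.kinetics
    events: list[EventSpec] = []

    for eid in range(cfg.n_events):
        identity = CAVEOLA if rng.uniform() < cfg.mixture.caveola_fraction else CCP
        d_cm2 = cfg.mobility_cm2_s[identity]

        if identity == CAVEOLA:
            aperture = float(rng.uniform(*geo.caveola_aperture_nm))
            margin = aperture / 2 + 300.0
            birth = 0
            ap = np.full(n, aperture)
            labels = frozenset({"plain"})
            closure = final_closure = None
            plateau = plateau_frames = None
            gap = disp = retention = None
            swelling = None
        else:
            aperture = float(rng.uniform(*geo.ccp_aperture_nm))
            labels = sample_motion_labels(rng, cfg.mixture)
            life = sample_ccp_lifetime_s(rng, kin.ccp_lifetime_mean_s,
                                         kin.ccp_lifetime_sd_s,
                                         *kin.ccp_lifetime_range_s)
            life_f = max(4, int(round(life / dt)))

            # the drawn lifetime spans birth -> final closure for every
            # event; a re-opening event splits it into first open period,
            # closed gap, and second open period
            gap_f = reopen_f2 = 0
            disp = retention = None
            gap = None
            if "reopen" in labels:
                gap_f = int(np.clip(round(rng.uniform(*kin.reopen_gap_s) / dt), 1, 7))
                if life_f < gap_f + 5:
                    life_f = gap_f + 5       # room for both open periods
                reopen_f2 = int(np.clip(round(rng.uniform(30.0, 100.0) / dt),
                                        2, life_f - gap_f - 3))
                disp = float(rng.uniform(*kin.reopen_displacement_nm))
                retention = float(np.clip(
                    rng.normal(*kin.reopen_retention), 0.14, 0.70))

            latest_birth = n - life_f - 5
            birth = int(rng.integers(1, max(2, latest_birth + 1)))
            final_closure = birth + life_f
            closure = final_closure - gap_f - reopen_f2 if gap_f else final_closure
            if final_closure > n - 2:          # movie too short: censor
                final_closure = None
                closure = closure if closure <= n - 2 else None
                labels = frozenset({"plain"})
                gap_f = reopen_f2 = 0
                disp = retention = None

            # aperture script: ramp from the range minimum to the event's
            # aperture over ~the first third of its life, then constant
            ap = np.full(n, np.nan)
            lo_ap = geo.ccp_aperture_nm[0]
            end_open1 = closure if closure is not None else n
            ramp_f = max(1, (end_open1 - birth) // 3)
            for f in range(birth, end_open1):
                frac = min(1.0, (f - birth) / ramp_f)
                ap[f] = lo_ap + frac * (aperture - lo_ap)
            if gap_f and final_closure is not None:
                gap = (closure, closure + gap_f)
                ap[closure + gap_f:final_closure] = aperture

            plateau = plateau_frames = None
            if "two_step" in labels and final_closure is not None:
                p_f = int(np.clip(round(rng.uniform(*kin.plateau_duration_s) / dt),
                                  1, 4))
                open_start = closure + gap_f if gap_f else birth
                p_f = min(p_f, max(1, final_closure - open_start - 3))
                plateau_frames = (final_closure - p_f, final_closure)
                ap[plateau_frames[0]:plateau_frames[1]] = geo.plateau_diameter_nm
                plateau = geo.plateau_diameter_nm

            swelling = None
            if "capping" in labels and final_closure is not None:
                sw_d = float(np.clip(rng.normal(geo.swelling_diameter_nm,
                                                geo.swelling_diameter_sd_nm),
                                     250.0, 520.0))
                sw_h = float(np.clip(rng.normal(geo.swelling_height_nm,
                                                geo.swelling_height_sd_nm),
                                     20.0, 60.0))
                swelling = SwellingSpec(
                    diameter_nm=sw_d, height_nm=sw_h,
                    direction=_unit_vector(rng),
                    onset_frame=max(birth + 1, final_closure - 2),
                    peak_frame=final_closure,
                    end_frame=min(n, final_closure + 3))
            margin = max(aperture, geo.swelling_diameter_nm) / 2 + 300.0

        # intrinsic trajectory, reflected into the usable field
        pos0 = np.array([rng.uniform(margin, width - margin),
                         rng.uniform(margin, height - margin)])
        traj = pos0 + sample_trajectory(d_cm2, (0.0, 0.0), n, dt, rng)
        lo = np.array([margin, margin])
        hi = np.array([width - margin, height - margin])
        traj = _reflect(traj, lo, hi)
        if gap is not None and disp is not None:
            # the pit re-opens at (closure position + drawn displacement):
            # the reported 13-113 nm is the total closed-to-reopened offset
            jump = np.array(_unit_vector(rng)) * disp
            traj = traj.copy()
            g0, g1 = gap
            traj[g1:] = traj[g0 - 1] + jump + (traj[g1:] - traj[g1])
            traj[g1:] = _reflect(traj[g1:], lo, hi)
            # during the closed state the residual coat drifts from the
            # closure position to the re-opening position
            for f in range(g0, g1):
                frac = (f - g0 + 1) / (g1 - g0 + 1)
                traj[f] = traj[g0 - 1] + frac * (traj[g1] - traj[g0 - 1])

        t_inv = birth * dt
        t_clo = final_closure * dt if final_closure is not None else None
        times = _channel_times(rng, cfg, t_inv, t_clo, (n - 1) * dt)

        events.append(EventSpec(
            event_id=eid, identity=identity,
            birth_frame=birth, invagination_frame=birth,
            closure_frame=closure, final_closure_frame=final_closure,
            motion_labels=labels, max_aperture_nm=aperture,
            aperture_nm=ap, trajectory_nm=traj,
            plateau_diameter_nm=plateau, plateau_frames=plateau_frames,
            reopen_gap_frames=gap, reopen_displacement_nm=disp,
            reopen_retention=retention, swelling=swelling,
            channel_times_s=times))
    return events
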