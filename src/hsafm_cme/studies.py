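"""Reference simulation studies.

Each function regenerates synthetic data at the package's study
conditions, runs the relevant part of the analysis chain, and returns
the recovered quantities.  The analysis drivers, the test suite and the
acceptance script all run these same computations.

Rendered-movie studies use the in-field mobility (D_IN_FIELD_CM2_S)
so events stay inside the 6.0 x 4.5 um^2 scan area for their whole
lifetime; trajectory-level studies use the reported per-class
diffusion coefficients directly (see docs/methods.md).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .config import (D_CAVEOLA_CM2_S, D_CCP_CM2_S, D_IN_FIELD_CM2_S,
                     SimulationConfig, preset_config)
from .detection import PitDetection, detect_movie
from .diffusion import (DiffusionEstimate, ensemble_msd, estimate_drift,
                        fit_diffusion, net_displacement_nm)
from .generate import generate_dataset
from .morphometry import tip_correct
from .motions import classify_closing, detect_swelling
from .pipeline import measure_track_diameters
from .tracking import PitTrack, link_tracks
from .trajectory import sample_trajectory

IN_FIELD_MOBILITY = {"CCP": D_IN_FIELD_CM2_S, "caveola": 1.0e-12}


def _derive_seed(seed: int, k: int) -> int:
    return int((seed * 1_000_003 + k) % (2 ** 31 - 1))


def tracks_from_trajectories(positions: list[np.ndarray]) -> list[PitTrack]:
    """Wrap raw per-frame (x, y) arrays as fully-detected tracks."""
    tracks = []
    for i, p in enumerate(positions):
        dets = [PitDetection(frame=f, x_nm=float(p[f, 0]), y_nm=float(p[f, 1]),
                             depth_nm=30.0, diameter_nm=250.0, score=30.0)
                for f in range(len(p))]
        tracks.append(PitTrack(track_id=i, detections=dets))
    return tracks


# ---------------------------------------------------------------------------
# trajectory-level studies (drift null, diffusion recovery)
# ---------------------------------------------------------------------------

def drift_null_study(seed: int, n_tracks: int = 2000, n_frames: int = 40,
                     dt_s: float = 10.0,
                     d_cm2_s: float = D_CCP_CM2_S) -> dict[str, float]:
    """Ensemble net displacement of drift-free Brownian pit trajectories.

    For randomly diffusing pits the mean first-to-last-frame displacement
    is zero; its magnitude over ``n_tracks`` trajectories is returned with
    the standard error implied by the diffusion coefficient.
    """
    rng = np.random.default_rng(seed)
    pos = [sample_trajectory(d_cm2_s, (0.0, 0.0), n_frames, dt_s, rng)
           for _ in range(n_tracks)]
    net = net_displacement_nm(tracks_from_trajectories(pos))
    per_axis_se = np.sqrt(2.0 * d_cm2_s * 1e14 * dt_s * (n_frames - 1)
                          / n_tracks)
    return {"net_displacement_nm": float(np.hypot(*net)),
            "per_axis_se_nm": float(per_axis_se), "n": n_tracks}


def diffusion_recovery_study(seed: int, identity: str = "CCP",
                             n_tracks: int = 200, n_frames: int = 30,
                             dt_s: float = 10.0,
                             drift_nm_per_frame: tuple[float, float] = (20.0, 0.0),
                             ) -> DiffusionEstimate:
    """Drift-corrected MSD recovery of a class diffusion coefficient.

    Simulates ``n_tracks`` trajectories at the class default mobility with
    a superimposed linear stage drift, estimates the drift from the pit
    ensemble, corrects, and fits MSD = 4 D t over the first four lags.
    """
    d_true = {"CCP": D_CCP_CM2_S, "caveola": D_CAVEOLA_CM2_S}[identity]
    rng = np.random.default_rng(seed)
    cum = np.outer(np.arange(n_frames), np.asarray(drift_nm_per_frame))
    pos = [sample_trajectory(d_true, (0.0, 0.0), n_frames, dt_s, rng) + cum
           for _ in range(n_tracks)]
    tracks = tracks_from_trajectories(pos)
    drift = estimate_drift(tracks, n_frames, method="ensemble")
    return fit_diffusion(ensemble_msd(tracks, drift, dt_s), identity=identity)


# ---------------------------------------------------------------------------
# rendered single-event studies (swelling morphometry, two-step plateau)
# ---------------------------------------------------------------------------

def _single_event_config(motion: str, seed: int,
                         **overrides) -> SimulationConfig:
    cfg = preset_config("untreated", n_frames=56, n_events=1,
                        grid_shape=(96, 96), channels=(), tip_radius_nm=0.0,
                        mobility_cm2_s=dict(IN_FIELD_MOBILITY), seed=seed,
                        **overrides)
    mix = {"capping": 0.0, "two_step": 0.0, "reopen": 0.0}
    mix[motion] = 1.0
    return cfg.replace(mixture=dataclasses.replace(cfg.mixture, **mix))


@dataclass
class SwellingStudyResult:
    diameters_nm: list[float]
    heights_nm: list[float]
    n_requested: int

    @property
    def mean_diameter_nm(self) -> float:
        return float(np.mean(self.diameters_nm))

    @property
    def mean_height_nm(self) -> float:
        return float(np.mean(self.heights_nm))


def capping_swelling_study(seed: int, n_events: int = 50) -> SwellingStudyResult:
    """Measured swelling geometry of rendered capping events (tip radius 0).

    Each event is rendered in its own movie at default noise; the swelling
    is located and measured with the section-profile operators around the
    tracked closure.
    """
    diams: list[float] = []
    heights: list[float] = []
    for k in range(n_events):
        cfg = _single_event_config("capping", _derive_seed(seed, k))
        bundle = generate_dataset(cfg)
        tracks = link_tracks(detect_movie(bundle.height.frames,
                                          cfg.pixel_size_nm,
                                          bundle.height.artifact_log))
        if not tracks:
            continue
        track = max(tracks, key=lambda t: len(t.detections))
        # every generated event carries a swelling, so the search gate is
        # lowered to measure (nearly) all of them: keeping the classifier's
        # conservative 20 nm gate would select against weak swellings and
        # bias the ensemble mean height upward
        record = detect_swelling(bundle.height.frames, track,
                                 cfg.pixel_size_nm, min_height_nm=10.0)
        if record is None:
            continue
        diams.append(record.diameter_nm)
        heights.append(record.height_nm)
    return SwellingStudyResult(diams, heights, n_events)


def two_step_plateau_study(seed: int, n_events: int = 50) -> dict[str, float]:
    """Median measured aperture during detected small-aperture plateaus."""
    plateau_diams: list[float] = []
    n_detected = 0
    for k in range(n_events):
        cfg = _single_event_config("two_step", _derive_seed(seed, k))
        bundle = generate_dataset(cfg)
        tracks = link_tracks(detect_movie(bundle.height.frames,
                                          cfg.pixel_size_nm,
                                          bundle.height.artifact_log))
        if not tracks:
            continue
        track = max(tracks, key=lambda t: len(t.detections))
        df = measure_track_diameters(bundle.height, track, cfg.tip_radius_nm)
        dmap = {int(r["frame"]):
                float(r["diameter_raw_nm"]) if np.isfinite(r["diameter_raw_nm"])
                else float(r["diameter_detection_nm"])
                for _, r in df.iterrows()}
        ann = classify_closing(track, None, dmap, cfg.n_frames,
                               cfg.frame_interval_s)
        if "two_step" in ann.labels and ann.plateau_frames is not None:
            n_detected += 1
            plateau_diams.extend(dmap[f] for f in range(*ann.plateau_frames)
                                 if f in dmap)
    return {"median_plateau_nm": float(np.median(plateau_diams)),
            "n_detected": n_detected, "n_frames_measured": len(plateau_diams)}


# ---------------------------------------------------------------------------
# population studies (motion mixture, lifetimes)
# ---------------------------------------------------------------------------

def motion_population_study(seed: int, n_events: int = 300,
                            events_per_movie: int = 15,
                            n_frames: int = 110,
                            preset: str = "untreated") -> dict[str, object]:
    """Closing-motion percentages recovered from rendered movies.

    Events are spread over several full-field movies at the configured
    preset mixture; the detection -> tracking -> classification chain is
    run and label percentages computed over all classified events.
    """
    from .pipeline import run_analyze

    n_movies = int(np.ceil(n_events / events_per_movie))
    counts = {"capping": 0, "two_step": 0, "reopen": 0, "plain": 0}
    n_classified = 0
    lifetimes: list[float] = []
    for k in range(n_movies):
        cfg = preset_config(preset, n_frames=n_frames,
                            n_events=events_per_movie, channels=(),
                            mobility_cm2_s=dict(IN_FIELD_MOBILITY),
                            seed=_derive_seed(seed, k))
        bundle = generate_dataset(cfg)
        result = run_analyze(bundle)
        for ann in result.annotations:
            n_classified += 1
            for lab in ann.labels:
                counts[lab] += 1
        lifetimes.extend(lt for lt in result.lifetimes["lifetime_s"]
                         if np.isfinite(lt))
    pct = {lab: 100.0 * c / n_classified for lab, c in counts.items()}
    return {"percentages": pct, "counts": counts, "n_classified": n_classified,
            "mean_lifetime_s": float(np.mean(lifetimes)),
            "n_lifetimes": len(lifetimes)}


def lifetime_recovery_study(seed: int, n_events: int = 200,
                            events_per_movie: int = 15,
                            n_frames: int = 120) -> dict[str, float]:
    """Mean tracked CCP lifetime (first detection to final closure).

    Movies are long enough that essentially no event is censored; tracks
    alive at either movie edge are excluded.
    """
    from .tracking import lifetime_and_rate

    n_movies = int(np.ceil(n_events / events_per_movie))
    lifetimes: list[float] = []
    n_censored = n_tracks = 0
    for k in range(n_movies):
        cfg = preset_config("untreated", n_frames=n_frames,
                            n_events=events_per_movie, channels=(),
                            mobility_cm2_s=dict(IN_FIELD_MOBILITY),
                            seed=_derive_seed(seed, k))
        bundle = generate_dataset(cfg)
        tracks = link_tracks(detect_movie(bundle.height.frames,
                                          cfg.pixel_size_nm,
                                          bundle.height.artifact_log))
        table, _ = lifetime_and_rate(tracks, cfg.scan_area_um2,
                                     n_frames * cfg.frame_interval_s,
                                     n_frames, cfg.frame_interval_s)
        n_tracks += len(table)
        n_censored += int(table["censored"].sum())
        lifetimes.extend(lt for lt in table["lifetime_s"] if np.isfinite(lt))
    return {"mean_lifetime_s": float(np.mean(lifetimes)),
            "n": len(lifetimes), "n_tracks": n_tracks,
            "censored_fraction": n_censored / max(1, n_tracks)}


def tip_correction_values() -> dict[str, float]:
    """Tip-correction arithmetic at the default 10 nm radius
    (the 150 -> 130 nm and 400 -> 380 nm mapping)."""
    return {"corrected_150_nm": tip_correct(150.0, 10.0),
            "corrected_400_nm": tip_correct(400.0, 10.0)}
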