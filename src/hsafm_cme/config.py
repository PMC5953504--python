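"""Simulation and analysis configuration.

All spatial quantities are in nanometres, times in seconds, diffusion
coefficients in cm^2/s at the API surface (converted internally).  The
defaults encode the study conditions the pipeline is built around: a
6.0 x 4.5 um^2 AFM scan (320 x 240 px at 18.75 nm/px) imaged every 10 s,
clathrin-coated pits (CCPs) of 150-400 nm aperture with a mean lifetime
of 81 s (SD 55 s, range 40-330 s), caveolae of 80-120 nm aperture that
stay open for the whole movie, and the untreated closing-motion mixture
(capping 54.9%, two-step 20%, re-opening 10%).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

NM2_PER_CM2 = 1.0e14

#: Diffusion coefficients reported for the two pit identities (cm^2/s).
D_CCP_CM2_S = 7.3e-9
D_CAVEOLA_CM2_S = 2.1e-9

#: Mobility used when events must stay inside the scan field of a rendered
#: movie for their whole lifetime (~80 nm RMS step per 10-s frame).  The
#: reported D values above imply multi-micrometre steps per frame, which is
#: incompatible with the 6.0 x 4.5 um^2 field; see docs/methods.md.
D_IN_FIELD_CM2_S = 3.0e-12


@dataclass
class NoiseParams:
    """Imaging noise for both modalities."""

    roughness_nm: float = 2.0          # membrane background sigma_z
    corr_length_nm: float = 100.0      # background correlation length
    photon_scale: float = 1000.0       # expected total photons from a spot at trace max
    background_photons: float = 20.0
    read_noise: float = 2.0            # Gaussian read noise, counts

    def validate(self) -> None:
        for name in ("roughness_nm", "corr_length_nm", "photon_scale",
                     "background_photons", "read_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"noise.{name} must be >= 0")


@dataclass
class ArtifactRates:
    tip_skip_per_frame: float = 0.01
    amplitude_step_per_frame: float = 0.002

    def validate(self) -> None:
        for name in ("tip_skip_per_frame", "amplitude_step_per_frame"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"artifact_rates.{name} must be in [0, 1]")


@dataclass
class GeometryParams:
    ccp_aperture_nm: tuple[float, float] = (150.0, 400.0)
    caveola_aperture_nm: tuple[float, float] = (80.0, 120.0)
    pit_depth_nm: float = 30.0
    swelling_diameter_nm: float = 378.0
    swelling_diameter_sd_nm: float = 62.0
    swelling_height_nm: float = 38.0
    swelling_height_sd_nm: float = 10.0
    plateau_diameter_nm: float = 120.0

    def validate(self) -> None:
        if self.pit_depth_nm <= 0:
            raise ValueError("pit_depth_nm must be > 0")
        for lo, hi in (self.ccp_aperture_nm, self.caveola_aperture_nm):
            if not 0 < lo <= hi:
                raise ValueError("aperture ranges must be positive and ordered")


@dataclass
class KineticsParams:
    """Event lifetime and phase-duration distributions (seconds)."""

    ccp_lifetime_mean_s: float = 81.0
    ccp_lifetime_sd_s: float = 55.0
    ccp_lifetime_range_s: tuple[float, float] = (40.0, 330.0)
    growing_range_s: tuple[float, float] = (40.0, 280.0)
    stable_range_s: tuple[float, float] = (0.0, 260.0)
    closing_range_s: tuple[float, float] = (20.0, 50.0)
    plateau_duration_s: tuple[float, float] = (10.0, 40.0)
    reopen_gap_s: tuple[float, float] = (10.0, 70.0)
    reopen_displacement_nm: tuple[float, float] = (13.0, 113.0)
    # clathrin retained during the closed gap of a re-opening event,
    # as a fraction of the trace maximum (mean, SD)
    reopen_retention: tuple[float, float] = (0.39, 0.18)

    def validate(self) -> None:
        if self.ccp_lifetime_mean_s <= 0 or self.ccp_lifetime_sd_s < 0:
            raise ValueError("lifetime mean must be > 0 and SD >= 0")


@dataclass
class MixtureParams:
    """Closing-motion mixture and pit-identity mixture.

    ``capping``/``two_step``/``reopen`` are marginal probabilities of each
    label among CCPs; labels are sampled independently except that capping
    and re-opening are mutually suppressed (the untreated data show an
    inverse relation).  ``caveola_fraction`` is the fraction of events that
    are caveolae rather than CCPs.
    """

    capping: float = 0.549
    two_step: float = 0.20
    reopen: float = 0.10
    caveola_fraction: float = 0.0

    def validate(self) -> None:
        for name in ("capping", "two_step", "reopen", "caveola_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"mixture.{name} must be in [0, 1]")
        if self.capping + self.reopen > 1.0 + 1e-12:
            raise ValueError("capping + reopen marginals exceed 1 "
                             "(they are mutually exclusive)")


@dataclass
class ChannelTiming:
    """Per-channel timing offsets (mean, SD in seconds).

    ``appearance`` is measured *before* its anchor (positive values mean the
    signal appears earlier); ``peak`` and ``disappearance`` are measured
    relative to pit closure (positive = after closure).
    """

    appearance_before_s: tuple[float, float]
    appearance_anchor: str  # "invagination" or "closure"
    peak_after_closure_s: tuple[float, float]
    disappearance_after_closure_s: tuple[float, float]


def default_channel_timings() -> dict[str, ChannelTiming]:
    return {
        "clathrin": ChannelTiming((34.0, 13.0), "invagination", (3.0, 7.0), (39.0, 13.0)),
        "epsin": ChannelTiming((47.0, 9.0), "invagination", (-14.0, 5.0), (13.0, 5.0)),
        "dynamin": ChannelTiming((25.0, 12.0), "invagination", (0.0, 1.0), (38.0, 9.0)),
        # actin rises relative to closure; its disappearance is not reported,
        # 30 +- 10 s after closure is this package's default.
        "actin": ChannelTiming((59.0, 18.0), "closure", (2.5, 7.0), (30.0, 10.0)),
        # caveolin marks caveolae, which persist; timing is nominal.
        "caveolin": ChannelTiming((0.0, 1.0), "invagination", (0.0, 1.0), (10.0, 5.0)),
    }


@dataclass
class SimulationConfig:
    grid_shape: tuple[int, int] = (240, 320)       # rows, cols
    pixel_size_nm: float = 18.75
    frame_interval_s: float = 10.0
    n_frames: int = 90
    n_events: int = 10
    mixture: MixtureParams = field(default_factory=MixtureParams)
    mobility_cm2_s: dict[str, float] = field(
        default_factory=lambda: {"CCP": D_CCP_CM2_S, "caveola": D_CAVEOLA_CM2_S})
    drift_velocity_nm: tuple[float, float] = (0.0, 0.0)  # per frame
    tip_radius_nm: float = 10.0
    noise: NoiseParams = field(default_factory=NoiseParams)
    artifact_rates: ArtifactRates = field(default_factory=ArtifactRates)
    timing: dict[str, ChannelTiming] = field(default_factory=default_channel_timings)
    geometry: GeometryParams = field(default_factory=GeometryParams)
    kinetics: KineticsParams = field(default_factory=KineticsParams)
    channels: tuple[str, ...] = ("clathrin",)
    optical_pixel_nm: float = 83.0
    psf_sigma_nm: float = 106.0
    seed: int = 0
    preset: str = "untreated"

    # -- geometry helpers ---------------------------------------------------
    @property
    def scan_extent_nm(self) -> tuple[float, float]:
        """(width, height) of the scan area in nm."""
        rows, cols = self.grid_shape
        return cols * self.pixel_size_nm, rows * self.pixel_size_nm

    @property
    def scan_area_um2(self) -> float:
        w, h = self.scan_extent_nm
        return (w / 1000.0) * (h / 1000.0)

    def validate(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")
        if self.n_frames < 1 or self.n_events < 0:
            raise ValueError("n_frames >= 1 and n_events >= 0 required")
        if self.tip_radius_nm < 0:
            raise ValueError("tip_radius_nm must be >= 0")
        for d in self.mobility_cm2_s.values():
            if d < 0:
                raise ValueError("diffusion coefficients must be >= 0")
        for ch in self.channels:
            if ch not in self.timing:
                raise ValueError(f"channel {ch!r} has no timing parameters")
        self.mixture.validate()
        self.noise.validate()
        self.artifact_rates.validate()
        self.geometry.validate()
        self.kinetics.validate()

    # -- (de)serialisation --------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        def conv(obj: Any) -> Any:
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: conv(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {k: conv(v) for k, v in obj.items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        d = {f.name: conv(getattr(self, f.name)) for f in dataclasses.fields(self)}
        d["timing"] = {ch: dataclasses.asdict(t) for ch, t in self.timing.items()}
        return conv(d)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        kwargs: dict[str, Any] = dict(data)

        def tup(x: Any) -> Any:
            return tuple(x) if isinstance(x, list) else x

        for key, sub in (("mixture", MixtureParams), ("noise", NoiseParams),
                         ("artifact_rates", ArtifactRates),
                         ("geometry", GeometryParams), ("kinetics", KineticsParams)):
            if key in kwargs and isinstance(kwargs[key], Mapping):
                kwargs[key] = sub(**{k: tup(v) for k, v in kwargs[key].items()})
        if "timing" in kwargs and isinstance(kwargs["timing"], Mapping):
            kwargs["timing"] = {
                ch: t if isinstance(t, ChannelTiming)
                else ChannelTiming(**{k: tup(v) for k, v in t.items()})
                for ch, t in kwargs["timing"].items()}
        for key in ("grid_shape", "drift_velocity_nm", "channels"):
            if key in kwargs:
                kwargs[key] = tup(kwargs[key])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def replace(self, **kwargs: Any) -> "SimulationConfig":
        cfg = dataclasses.replace(self, **kwargs)
        cfg.validate()
        return cfg


# ---------------------------------------------------------------------------
# Perturbation presets: re-weighted motion mixtures and phase durations.
# Capping/re-open percentages follow the reported inhibitor effects
# (capping 56% -> 0.4% under cytochalasin B, -> 3% under CK666; re-open
# 20% -> 67% / 47%; dynamin knockdown capping 59% -> 35%).  Two-step
# changes are shown only graphically in the source data; values here are
# fixed package choices.
# ---------------------------------------------------------------------------

def _preset_overrides() -> dict[str, dict[str, Any]]:
    return {
        "untreated": {},
        "cytoB": {
            "mixture": MixtureParams(capping=0.004, two_step=0.40, reopen=0.67),
            "kinetics": dataclasses.replace(
                KineticsParams(), growing_range_s=(0.0, 40.0),
                stable_range_s=(10.0, 120.0), closing_range_s=(10.0, 35.0),
                ccp_lifetime_mean_s=55.0, ccp_lifetime_sd_s=30.0,
                ccp_lifetime_range_s=(20.0, 200.0)),
        },
        "CK666": {
            "mixture": MixtureParams(capping=0.03, two_step=0.35, reopen=0.47),
            "kinetics": dataclasses.replace(
                KineticsParams(), growing_range_s=(10.0, 120.0),
                ccp_lifetime_mean_s=65.0, ccp_lifetime_sd_s=40.0,
                ccp_lifetime_range_s=(30.0, 250.0)),
        },
        "jasp": {
            "mixture": MixtureParams(capping=0.35, two_step=0.20, reopen=0.25),
            "kinetics": dataclasses.replace(
                KineticsParams(), ccp_lifetime_mean_s=120.0, ccp_lifetime_sd_s=70.0,
                ccp_lifetime_range_s=(40.0, 400.0)),
        },
        "siDNM2": {
            "mixture": MixtureParams(capping=0.35, two_step=0.45, reopen=0.15),
            "kinetics": dataclasses.replace(
                KineticsParams(), plateau_duration_s=(20.0, 80.0),
                ccp_lifetime_mean_s=110.0, ccp_lifetime_sd_s=60.0,
                ccp_lifetime_range_s=(40.0, 400.0)),
        },
    }


PRESETS = tuple(_preset_overrides())


def preset_config(name: str = "untreated", **kwargs: Any) -> SimulationConfig:
    """Return a SimulationConfig for a named condition preset."""
    overrides = _preset_overrides()
    if name not in overrides:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}")
    cfg = SimulationConfig(preset=name, **overrides[name])
    if kwargs:
        cfg = cfg.replace(**kwargs)
    cfg.validate()
    return cfg
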