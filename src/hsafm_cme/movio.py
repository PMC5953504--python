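"""Movie containers and TIFF + JSON-sidecar input/output.

AFM height movies are stored as multi-page 32-bit float TIFFs (heights in
nm); fluorescence channels as multi-page uint16 TIFFs.  Every stack is
accompanied by a ``<name>.json`` sidecar holding the metadata the pixels
cannot carry: pixel size, frame interval, kind, channel name and the scan
corner coordinates.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import tifffile


class MovieFormatError(ValueError):
    """Raised for malformed stacks or missing sidecar metadata."""


@dataclass
class HeightMovie:
    """Time-ordered stack of AFM height grids (nm)."""

    frames: np.ndarray                  # (n_frames, rows, cols) float
    frame_interval_s: float
    pixel_size_nm: float
    artifact_log: list[dict[str, Any]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float32)
        if self.frames.ndim != 3:
            raise MovieFormatError("height movie must be a 3-D stack")
        if not np.all(np.isfinite(self.frames)):
            raise MovieFormatError("height movie contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s


@dataclass
class FluorMovie:
    """Stack of fluorescence intensity grids for one channel."""

    frames: np.ndarray                  # (n_frames, rows, cols) uint16
    frame_interval_s: float
    pixel_size_nm: float                # optical pixel
    channel: str = "clathrin"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise MovieFormatError("fluorescence movie must be a 3-D stack")
        if np.any(self.frames.astype(np.int64) < 0):
            raise MovieFormatError("fluorescence intensities must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


_REQUIRED_KEYS = ("kind", "pixel_size_nm", "frame_interval_s")


def _sidecar_path(path: str) -> str:
    return os.path.splitext(path)[0] + ".json"


def write_movie(movie: HeightMovie | FluorMovie, path: str,
                extra_meta: dict[str, Any] | None = None) -> None:
    """Write a movie stack as multi-page TIFF with a JSON sidecar."""
    if isinstance(movie, HeightMovie):
        data = movie.frames.astype(np.float32)
        meta: dict[str, Any] = {"kind": "height",
                                "artifact_log": movie.artifact_log}
    else:
        data = movie.frames.astype(np.uint16)
        meta = {"kind": "fluor", "channel": movie.channel}
    meta.update({"pixel_size_nm": movie.pixel_size_nm,
                 "frame_interval_s": movie.frame_interval_s,
                 "n_frames": int(data.shape[0]),
                 "shape": list(data.shape[1:])})
    if extra_meta:
        meta.update(extra_meta)
    tifffile.imwrite(path, data, photometric="minisblack")
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=1)


def read_movie(path: str,
               metadata: dict[str, Any] | None = None) -> HeightMovie | FluorMovie:
    """Read a movie stack written by :func:`write_movie`.

    ``metadata`` may supply sidecar fields when no sidecar file exists.
    """
    if metadata is None:
        sidecar = _sidecar_path(path)
        if not os.path.exists(sidecar):
            raise MovieFormatError(
                f"no sidecar metadata for {path!r}; required keys: "
                f"{', '.join(_REQUIRED_KEYS)}")
        with open(sidecar) as fh:
            metadata = json.load(fh)
    missing = [k for k in _REQUIRED_KEYS if k not in metadata]
    if missing:
        raise MovieFormatError(f"sidecar missing required keys: {missing}")

    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise MovieFormatError(f"expected a 2-D page stack, got shape {data.shape}")

    if metadata["kind"] == "height":
        return HeightMovie(frames=data.astype(np.float32),
                           frame_interval_s=metadata["frame_interval_s"],
                           pixel_size_nm=metadata["pixel_size_nm"],
                           artifact_log=metadata.get("artifact_log", []))
    if metadata["kind"] == "fluor":
        return FluorMovie(frames=data.astype(np.uint16),
                          frame_interval_s=metadata["frame_interval_s"],
                          pixel_size_nm=metadata["pixel_size_nm"],
                          channel=metadata.get("channel", "unknown"))
    raise MovieFormatError(f"unknown movie kind {metadata['kind']!r}")
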