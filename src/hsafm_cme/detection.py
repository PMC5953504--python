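"""Per-frame detection of membrane invaginations in AFM height images.

A pit is a connected region lying at least ``depth_min`` below the local
baseline (median height in a ~750 nm neighbourhood).  Merged regions are
split at their regional depth maxima by a watershed; each detection gets
a depth-weighted centroid in scan-local nm, its maximum depth, and a
preliminary equivalent-circle diameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.segmentation import watershed


@dataclass
class PitDetection:
    frame: int
    x_nm: float
    y_nm: float
    depth_nm: float
    diameter_nm: float
    score: float

    def position(self) -> np.ndarray:
        return np.array([self.x_nm, self.y_nm])


def local_baseline(grid: np.ndarray, pixel_size_nm: float,
                   window_nm: float = 750.0, downsample: int = 4) -> np.ndarray:
    """Median baseline height in a sliding window, computed on a
    decimated grid for speed and upsampled back."""
    ds = max(1, downsample)
    small = grid[::ds, ::ds]
    k = max(3, int(round(window_nm / (pixel_size_nm * ds))) | 1)
    med = ndimage.median_filter(small.astype(float), size=k, mode="nearest")
    if ds == 1:
        return med
    up = ndimage.zoom(med, ds, order=1, mode="nearest", grid_mode=True)
    rows, cols = grid.shape
    if up.shape[0] < rows or up.shape[1] < cols:
        up = np.pad(up, ((0, max(0, rows - up.shape[0])),
                         (0, max(0, cols - up.shape[1]))), mode="edge")
    return up[:rows, :cols]


def detect_pits(grid: np.ndarray, pixel_size_nm: float,
                depth_min_nm: float = 10.0, min_diameter_nm: float = 60.0,
                baseline_window_nm: float = 750.0,
                split_min_distance_nm: float = 150.0,
                artifact_rows: list[int] | None = None,
                frame: int = 0) -> list[PitDetection]:
    """Detect pits in one height frame (empty list when none qualify)."""
    baseline = local_baseline(grid, pixel_size_nm, baseline_window_nm)
    depth = baseline - grid
    mask = depth >= depth_min_nm
    if artifact_rows:
        rows = [r for r in artifact_rows if 0 <= r < grid.shape[0]]
        mask[rows, :] = False
    if not mask.any():
        return []

    min_dist_px = max(1, int(round(split_min_distance_nm / pixel_size_nm)))
    labels, n = ndimage.label(mask)
    peaks = peak_local_max(np.where(mask, depth, 0.0), min_distance=min_dist_px,
                           labels=labels, exclude_border=False)
    if len(peaks) == 0:
        return []
    markers = np.zeros_like(labels)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    segments = watershed(-depth, markers=markers, mask=mask)

    detections: list[PitDetection] = []
    min_area_px = np.pi * (min_diameter_nm / 2.0) ** 2 / pixel_size_nm ** 2
    for idx in range(1, int(segments.max()) + 1):
        region = segments == idx
        area = int(region.sum())
        if area < min_area_px:
            continue
        w = np.where(region, depth, 0.0)
        total = w.sum()
        rr, cc = np.nonzero(region)
        x = float(((cc + 0.5) * w[region]).sum() / total) * pixel_size_nm
        y = float(((rr + 0.5) * w[region]).sum() / total) * pixel_size_nm
        d_max = float(w.max())
        diameter = 2.0 * np.sqrt(area / np.pi) * pixel_size_nm
        detections.append(PitDetection(frame=frame, x_nm=x, y_nm=y,
                                       depth_nm=d_max, diameter_nm=diameter,
                                       score=d_max))
    return detections


def artifact_rows_by_frame(artifact_log: list[dict]) -> dict[int, list[int]]:
    """Index tip-skip rows by frame from a generator/IO artifact log."""
    out: dict[int, list[int]] = {}
    for entry in artifact_log or []:
        if entry.get("type") == "tip_skip":
            out.setdefault(int(entry["frame"]), []).extend(entry["rows"])
    return out


def detect_movie(frames: np.ndarray, pixel_size_nm: float,
                 artifact_log: list[dict] | None = None,
                 **kwargs) -> list[list[PitDetection]]:
    """Run :func:`detect_pits` on every frame of a stack."""
    rows_by_frame = artifact_rows_by_frame(artifact_log or [])
    return [detect_pits(frames[t], pixel_size_nm,
                        artifact_rows=rows_by_frame.get(t), frame=t, **kwargs)
            for t in range(frames.shape[0])]
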