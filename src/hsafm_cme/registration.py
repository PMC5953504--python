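"""AFM <-> confocal co-registration via the probe-origin procedure.

The AFM probe is parked on the glass and its autofluorescence imaged;
the spot centre defines the origin of a common coordinate frame (nm,
+y upward).  The AFM scan area occupies a known rectangle in that frame
(corners (-3, 2.25) ... (3, -2.25) um by default), so AFM pixels,
optical pixels and scan-local nm positions can all be mapped into one
frame and pit/spot centroid offsets measured directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


class NoSpotError(ValueError):
    """No pixel rises above the background threshold."""


class AmbiguousSpotError(ValueError):
    """Several disconnected regions share the global maximum."""


class GeometryError(ValueError):
    """Degenerate scan geometry."""


DEFAULT_CORNERS_UM = ((-3.0, 2.25), (3.0, 2.25), (3.0, -2.25), (-3.0, -2.25))


@dataclass
class ScanGeometry:
    """Placement of the AFM scan area in the optical frame."""

    corners_um: tuple = DEFAULT_CORNERS_UM      # TL, TR, BR, BL (x, y)
    afm_pixel_nm: float = 18.75
    optical_pixel_nm: float = 83.0
    probe_origin_px: tuple[float, float] = (0.0, 0.0)   # (col, row), optical

    def validate(self) -> None:
        if self.afm_pixel_nm <= 0 or self.optical_pixel_nm <= 0:
            raise GeometryError("pixel sizes must be > 0")
        (x0, y0), (x1, y1), (x2, y2), (x3, y3) = self.corners_um
        if not (x0 == x3 and x1 == x2 and y0 == y1 and y2 == y3):
            raise GeometryError("corners must form an axis-aligned rectangle")
        if x1 <= x0 or y0 <= y2:
            raise GeometryError("degenerate or flipped scan rectangle")

    @property
    def top_left_nm(self) -> tuple[float, float]:
        return (self.corners_um[0][0] * 1000.0, self.corners_um[0][1] * 1000.0)


@dataclass
class RegistrationTransform:
    """Invertible maps between pixel grids and the common nm frame."""

    geometry: ScanGeometry
    time_offset_s: float = 0.0

    # -- AFM pixels (col, row; pixel centres) -------------------------------
    def afm_px_to_nm(self, colrow: np.ndarray) -> np.ndarray:
        cr = np.asarray(colrow, dtype=float)
        xtl, ytl = self.geometry.top_left_nm
        apx = self.geometry.afm_pixel_nm
        out = np.empty_like(cr)
        out[..., 0] = xtl + (cr[..., 0] + 0.5) * apx
        out[..., 1] = ytl - (cr[..., 1] + 0.5) * apx
        return out

    def nm_to_afm_px(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, dtype=float)
        xtl, ytl = self.geometry.top_left_nm
        apx = self.geometry.afm_pixel_nm
        out = np.empty_like(xy)
        out[..., 0] = (xy[..., 0] - xtl) / apx - 0.5
        out[..., 1] = (ytl - xy[..., 1]) / apx - 0.5
        return out

    # -- scan-local nm (origin at top-left corner, y down) ------------------
    def scanlocal_to_nm(self, xy_local: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy_local, dtype=float)
        xtl, ytl = self.geometry.top_left_nm
        out = np.empty_like(xy)
        out[..., 0] = xtl + xy[..., 0]
        out[..., 1] = ytl - xy[..., 1]
        return out

    def nm_to_scanlocal(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, dtype=float)
        xtl, ytl = self.geometry.top_left_nm
        out = np.empty_like(xy)
        out[..., 0] = xy[..., 0] - xtl
        out[..., 1] = ytl - xy[..., 1]
        return out

    # -- optical pixels (col, row) ------------------------------------------
    def optical_px_to_nm(self, colrow: np.ndarray) -> np.ndarray:
        cr = np.asarray(colrow, dtype=float)
        x0, y0 = self.geometry.probe_origin_px
        opx = self.geometry.optical_pixel_nm
        out = np.empty_like(cr)
        out[..., 0] = (cr[..., 0] - x0) * opx
        out[..., 1] = -(cr[..., 1] - y0) * opx
        return out

    def nm_to_optical_px(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, dtype=float)
        x0, y0 = self.geometry.probe_origin_px
        opx = self.geometry.optical_pixel_nm
        out = np.empty_like(xy)
        out[..., 0] = xy[..., 0] / opx + x0
        out[..., 1] = -xy[..., 1] / opx + y0
        return out


def build_transform(geometry: ScanGeometry,
                    time_offset_s: float = 0.0) -> RegistrationTransform:
    """Validate the geometry and build the invertible transform."""
    geometry.validate()
    return RegistrationTransform(geometry=geometry, time_offset_s=time_offset_s)


# ---------------------------------------------------------------------------
# probe-origin localisation
# ---------------------------------------------------------------------------

def locate_probe_origin(image: np.ndarray,
                        background_window_px: int = 31) -> tuple[float, float]:
    """Sub-pixel (col, row) of the probe's autofluorescence spot.

    A median-filtered background is removed, pixels above
    ``median + 3 * MAD`` of the residual are segmented, and the
    intensity-weighted centroid of the brightest connected region is
    returned.
    """
    img = np.asarray(image, dtype=float)
    bg = ndimage.median_filter(img, size=background_window_px)
    resid = img - bg
    med = np.median(resid)
    mad = np.median(np.abs(resid - med))
    if mad > 0:
        mask = resid > med + 3.0 * mad
    else:
        # dark frame with isolated bright pixels: fall back to half-max
        mask = resid > med + 0.5 * (resid.max() - med)
    if resid.max() <= med or not mask.any():
        raise NoSpotError("no pixel above the background threshold")
    labels, n = ndimage.label(mask)
    peaks = ndimage.maximum(resid, labels, index=np.arange(1, n + 1))
    top = float(np.max(peaks))
    winners = np.flatnonzero(np.isclose(peaks, top, rtol=0, atol=1e-12))
    if len(winners) > 1:
        raise AmbiguousSpotError(f"{len(winners)} regions share the maximum")
    region = labels == (winners[0] + 1)
    w = np.where(region, resid - med, 0.0)
    total = w.sum()
    rows, cols = np.nonzero(region)
    row_c = float((rows * w[region]).sum() / total)
    col_c = float((cols * w[region]).sum() / total)
    return (col_c, row_c)


# ---------------------------------------------------------------------------
# spot centroids and offsets
# ---------------------------------------------------------------------------

def spot_centroid(frame: np.ndarray, center_colrow: tuple[float, float],
                  window_px: int = 5,
                  noise_sigma: float | None = None
                  ) -> tuple[tuple[float, float], float] | None:
    """Background-subtracted centroid of a spot near an expected position.

    Returns ``((col, row), net_intensity)`` or None when the window peak
    does not exceed the local background by 3 sigma.  The background is
    the median of a surrounding ring; sigma defaults to a robust estimate
    from the whole frame.
    """
    img = np.asarray(frame, dtype=float)
    rows, cols = img.shape
    cx, cy = center_colrow
    r = window_px
    c0, c1 = int(round(cx)) - r, int(round(cx)) + r + 1
    r0, r1 = int(round(cy)) - r, int(round(cy)) + r + 1
    c0, c1 = max(0, c0), min(cols, c1)
    r0, r1 = max(0, r0), min(rows, r1)
    if c1 - c0 < 2 or r1 - r0 < 2:
        return None
    win = img[r0:r1, c0:c1]
    R = r + 3
    cc0, cc1 = max(0, int(round(cx)) - R), min(cols, int(round(cx)) + R + 1)
    rr0, rr1 = max(0, int(round(cy)) - R), min(rows, int(round(cy)) + R + 1)
    ring = img[rr0:rr1, cc0:cc1].copy()
    ring[r0 - rr0:r1 - rr0, c0 - cc0:c1 - cc0] = np.nan
    bg = float(np.nanmedian(ring))
    if noise_sigma is None:
        mad = np.median(np.abs(img - np.median(img)))
        noise_sigma = 1.4826 * mad if mad > 0 else img.std() or 1.0
    if win.max() - bg < 3.0 * noise_sigma:
        return None
    w = np.clip(win - bg, 0.0, None)
    total = w.sum()
    if total <= 0:
        return None
    ys, xs = np.mgrid[r0:r1, c0:c1]
    return ((float((xs * w).sum() / total), float((ys * w).sum() / total)),
            float(total))


@dataclass
class OffsetMeasurement:
    """Centroid offset between a membrane pit and its fluorescent spot."""

    event_id: int
    frame: int
    afm_centroid_nm: tuple[float, float]
    fluor_centroid_nm: tuple[float, float]
    dx_nm: float = field(init=False)
    dy_nm: float = field(init=False)
    d_nm: float = field(init=False)

    def __post_init__(self) -> None:
        self.dx_nm = self.fluor_centroid_nm[0] - self.afm_centroid_nm[0]
        self.dy_nm = self.fluor_centroid_nm[1] - self.afm_centroid_nm[1]
        self.d_nm = float(np.hypot(self.dx_nm, self.dy_nm))


def measure_offset(afm_centroid_nm: tuple[float, float],
                   fluor_centroid_nm: tuple[float, float],
                   event_id: int = -1, frame: int = -1) -> OffsetMeasurement:
    """Componentwise and Euclidean offset between two centroids (common nm)."""
    return OffsetMeasurement(event_id=event_id, frame=frame,
                             afm_centroid_nm=tuple(afm_centroid_nm),
                             fluor_centroid_nm=tuple(fluor_centroid_nm))
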