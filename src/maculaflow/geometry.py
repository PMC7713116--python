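"""Shared raster/volume data model, ROI construction, unit conversions,
and phantom-grade RPE segmentation with a pathology-excluding floor fit.

Conventions
-----------
* Arrays are row-major with origin at the top-left; pixel/voxel centers sit
  at integer grid coordinates.
* The depth axis of a volume runs vitreous -> choroid; axial positions are
  expressed in micrometres from the top of the volume (voxel ``k`` is at
  ``k * axial_pitch_um``).
* All physical quantities at API boundaries are micrometres or millimetres,
  never pixels, to avoid silent scale bugs between the 6 mm field of view
  and the 500-pixel grid (12 um/px).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


class GeometryError(ValueError):
    """Raised for invalid geometric specifications or degenerate inputs."""


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Raster:
    """2-D en-face intensity grid with a lateral pixel pitch in um/pixel."""

    values: np.ndarray
    lateral_pitch_um: float

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape[0] < 1 or v.shape[1] < 1:
            raise GeometryError("raster must be a non-empty 2-D array")
        if not np.all(np.isfinite(v)):
            raise GeometryError("raster intensities must be finite")
        if np.any(v < 0):
            raise GeometryError("raster intensities must be non-negative")
        if not self.lateral_pitch_um > 0:
            raise GeometryError("lateral pitch must be positive")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def pixel_area_um2(self) -> float:
        return self.lateral_pitch_um ** 2


@dataclass(frozen=True)
class OctVolume:
    """3-D structural OCT grid, axes (depth, rows, cols)."""

    values: np.ndarray
    axial_pitch_um: float
    lateral_pitch_um: float

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 3 or min(v.shape) < 1:
            raise GeometryError("volume must be a non-empty 3-D array")
        if not (self.axial_pitch_um > 0 and self.lateral_pitch_um > 0):
            raise GeometryError("pitches must be positive")
        object.__setattr__(self, "values", v)

    @property
    def depth_um(self) -> float:
        """Axial extent covered by voxel centers."""
        return (self.values.shape[0] - 1) * self.axial_pitch_um

    @property
    def lateral_shape(self) -> tuple[int, int]:
        return self.values.shape[1:]


@dataclass(frozen=True)
class Surface:
    """Per-A-scan axial position map in um from the top of the volume."""

    z_um: np.ndarray

    def __post_init__(self):
        z = np.asarray(self.z_um, dtype=float)
        if z.ndim != 2:
            raise GeometryError("surface must be 2-D")
        if not np.all(np.isfinite(z)):
            raise GeometryError("surface must be finite everywhere")
        object.__setattr__(self, "z_um", z)

    @property
    def shape(self) -> tuple[int, int]:
        return self.z_um.shape


@dataclass(frozen=True)
class RoiSpec:
    """Fovea-centered circular region of interest.

    The fovea is located manually on real scans; the phantom knows it by
    construction. ``diameter_mm`` defaults to the 5.0 mm analysis circle.
    """

    center_row: float
    center_col: float
    diameter_mm: float = 5.0


@dataclass
class RegionMasks:
    """ROI partition into drusen / drusen-free plus a vessel-exclusion mask.

    Invariants: ``drusen | drusen_free == roi``, ``drusen & drusen_free`` is
    empty, and ``vessel_excluded`` is a subset of ``roi``.
    """

    roi: np.ndarray
    drusen: np.ndarray
    drusen_free: np.ndarray
    vessel_excluded: np.ndarray = None

    def __post_init__(self):
        if self.vessel_excluded is None:
            self.vessel_excluded = np.zeros_like(self.roi, dtype=bool)
        for name in ("roi", "drusen", "drusen_free", "vessel_excluded"):
            m = np.asarray(getattr(self, name), dtype=bool)
            setattr(self, name, m)
            if m.shape != self.roi.shape:
                raise GeometryError("all masks must share one grid")
        if np.any(self.drusen & self.drusen_free):
            raise GeometryError("drusen and drusen-free masks overlap")
        if not np.array_equal(self.drusen | self.drusen_free, self.roi):
            raise GeometryError("drusen/drusen-free must partition the ROI")
        # vessels outside the ROI are irrelevant; clip to keep the invariant
        self.vessel_excluded = self.vessel_excluded & self.roi


# ---------------------------------------------------------------------------
# ROI construction and unit conversions
# ---------------------------------------------------------------------------

def circular_roi_mask(grid_shape: tuple[int, int], lateral_pitch_um: float,
                      roi: RoiSpec) -> np.ndarray:
    """Boolean mask of the fovea-centered circle.

    A pixel belongs to the ROI iff its center lies within ``diameter/2`` of
    the ROI center. The circle must fit wholly inside the grid; violation
    signals a mis-specified fovea location and is rejected.
    """
    if roi.diameter_mm <= 0:
        raise GeometryError("ROI diameter must be positive")
    if lateral_pitch_um <= 0:
        raise GeometryError("pitch must be positive")
    rows, cols = grid_shape
    radius_px = roi.diameter_mm * 1000.0 / 2.0 / lateral_pitch_um
    if (roi.center_row - radius_px < 0 or roi.center_col - radius_px < 0
            or roi.center_row + radius_px > rows - 1
            or roi.center_col + radius_px > cols - 1):
        raise GeometryError(
            f"{roi.diameter_mm} mm ROI centered at "
            f"({roi.center_row}, {roi.center_col}) exceeds the "
            f"{rows}x{cols} grid")
    rr = np.arange(rows)[:, None] - roi.center_row
    cc = np.arange(cols)[None, :] - roi.center_col
    return rr * rr + cc * cc <= radius_px * radius_px


def equiv_diameter_um(area_um2):
    """Diameter of the circle with the same area: ``2 * sqrt(area / pi)``."""
    area = np.asarray(area_um2, dtype=float)
    if np.any(area < 0):
        raise GeometryError("area must be non-negative")
    out = 2.0 * np.sqrt(area / math.pi)
    return float(out) if np.isscalar(area_um2) else out


def um2_to_pixels(area_um2: float, lateral_pitch_um: float) -> float:
    """Convert an area in um^2 to a (fractional) pixel count."""
    if area_um2 < 0:
        raise GeometryError("area must be non-negative")
    if lateral_pitch_um <= 0:
        raise GeometryError("pitch must be positive")
    return area_um2 / lateral_pitch_um ** 2


# ---------------------------------------------------------------------------
# RPE segmentation (phantom-grade) and the pathology-excluding floor fit
# ---------------------------------------------------------------------------

def segment_rpe(volume: OctVolume, depth_smooth_um: float = 10.0,
                max_flagged_fraction: float = 0.05,
                median_size: int = 5,
                lateral_smooth_px: float = 1.0) -> Surface:
    """Locate the RPE as the brightest depth-smoothed band per A-scan.

    Each A-scan profile is smoothed along depth with a Gaussian of
    ``depth_smooth_um`` (and lightly across neighboring A-scans, since
    speckle is uncorrelated laterally while the surface is smooth); the
    surface is the sub-voxel maximum (parabolic refinement of the argmax),
    median-filtered laterally to suppress isolated picks of other bright
    bands. A-scans with no intensity variation carry no localizable band
    and are flagged; if more than ``max_flagged_fraction`` of A-scans are
    flagged the surface is rejected.
    """
    v = np.asarray(volume.values)
    if not np.issubdtype(v.dtype, np.floating):
        v = v.astype(np.float64)
    flat = np.ptp(v, axis=0) == 0
    if flat.mean() > max_flagged_fraction:
        raise GeometryError(
            f"{100 * flat.mean():.1f}% of A-scans have no intensity "
            "variation; RPE surface rejected")
    sigma = depth_smooth_um / volume.axial_pitch_um
    prof = ndimage.gaussian_filter(
        v, sigma=(sigma, lateral_smooth_px, lateral_smooth_px),
        mode="nearest")
    # the RPE is the deepest strong band: among local maxima within
    # strong_fraction of the profile peak, take the deepest (the EZ band is
    # brighter only through noise and always lies above the RPE)
    strong_fraction = 0.8
    depth = prof.shape[0]
    inner = prof[1:-1]
    is_peak = (inner >= prof[:-2]) & (inner >= prof[2:]) & (
        inner >= strong_fraction * prof.max(axis=0))
    rev_idx = np.argmax(is_peak[::-1], axis=0)
    has_peak = is_peak.any(axis=0)
    k = np.where(has_peak, (is_peak.shape[0] - 1 - rev_idx) + 1,
                 np.argmax(prof, axis=0))
    # parabolic sub-voxel refinement around the discrete peak
    kc = np.clip(k, 1, depth - 2)
    take = np.take_along_axis
    y0 = take(prof, (kc - 1)[None], axis=0)[0]
    y1 = take(prof, kc[None], axis=0)[0]
    y2 = take(prof, (kc + 1)[None], axis=0)[0]
    denom = y0 - 2 * y1 + y2
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = 0.5 * (y0 - y2) / denom
    delta = np.where((np.abs(denom) > 1e-12) & (np.abs(delta) <= 1.0),
                     delta, 0.0)
    idx = np.where((k >= 1) & (k <= depth - 2), k + delta,
                   k.astype(float))
    if flat.any():
        idx[flat] = np.median(idx[~flat])
    idx = ndimage.median_filter(idx, size=median_size, mode="nearest")
    return Surface(idx * volume.axial_pitch_um)


def _poly2_design(shape: tuple[int, int]) -> np.ndarray:
    """Total-degree-2 design matrix on coordinates normalized to [-1, 1]."""
    rows, cols = shape
    r = np.linspace(-1.0, 1.0, rows)[:, None] * np.ones((1, cols))
    c = np.ones((rows, 1)) * np.linspace(-1.0, 1.0, cols)[None, :]
    r, c = r.ravel(), c.ravel()
    return np.column_stack([np.ones_like(r), r, c, r * r, r * c, c * c])


def fit_rpe_floor(rpe: Surface, elevation_tol_um: float = 10.0,
                  max_iter: int = 10,
                  min_retained_fraction: float = 0.4) -> Surface:
    """Fit the smooth sub-RPE floor (Bruch's-membrane proxy) to the RPE.

    A total-degree-2 polynomial surface is fit by least squares; points
    elevated above the fit (toward the vitreous, i.e. candidate drusen) by
    more than ``elevation_tol_um`` are discarded and the fit repeated until
    the retained set is stable. If more than 60% of points are rejected as
    pathology the fit is declared unreliable.
    """
    z = rpe.z_um.ravel()
    X = _poly2_design(rpe.shape)
    keep = np.ones(z.size, dtype=bool)
    for _ in range(max_iter):
        coef, *_ = np.linalg.lstsq(X[keep], z[keep], rcond=None)
        fit = X @ coef
        # elevated = RPE nearer the vitreous (smaller z) than the fit
        new_keep = (fit - z) <= elevation_tol_um
        if new_keep.sum() < min_retained_fraction * z.size:
            raise GeometryError(
                "floor fit unreliable: pathology covers more than "
                f"{100 * (1 - min_retained_fraction):.0f}% of the surface")
        if np.array_equal(new_keep, keep):
            break
        keep = new_keep
    coef, *_ = np.linalg.lstsq(X[keep], z[keep], rcond=None)
    return Surface((X @ coef).reshape(rpe.shape))


def resample_raster(values: np.ndarray, from_pitch_um: float,
                    to_shape: tuple[int, int], to_pitch_um: float,
                    order: int = 1) -> np.ndarray:
    """Resample an en-face raster onto a grid with a different pixel pitch.

    Both grids are anchored at the top-left pixel center. Used to carry
    masks/fields between the structural-volume grid and the (finer) CC grid.
    """
    rows, cols = to_shape
    rr = np.arange(rows) * to_pitch_um / from_pitch_um
    cc = np.arange(cols) * to_pitch_um / from_pitch_um
    coords = np.meshgrid(rr, cc, indexing="ij")
    return ndimage.map_coordinates(
        np.asarray(values, dtype=float), coords, order=order, mode="nearest")
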