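"""Choriocapillaris (CC) flow-deficit quantification.

Pipeline: extract the CC en-face slab (20 um, 29 um under the RPE-fit
floor), compensate the flow image with the structural image to undo
drusen/media shadowing, exclude retinal-vessel projection artifacts,
binarize with the Phansalkar local threshold (window radius 3 px), drop
isolated deficits with equivalent diameter < 24 um (presumed noise), and
report FD%, mean deficit size and deficit count per analysis region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .geometry import Raster, Surface, OctVolume, equiv_diameter_um


class CcFlowError(ValueError):
    pass


@dataclass(frozen=True)
class PhansalkarParams:
    """Phansalkar local-threshold constants, applied on [0, 1] intensities.

    ``window_radius_px`` is the radius of the circular neighborhood; the
    remaining constants are the published defaults of the method.
    """

    window_radius_px: int = 3
    p: float = 2.0
    q: float = 10.0
    k: float = 0.25
    R: float = 0.5

    def __post_init__(self):
        if self.window_radius_px < 1:
            raise CcFlowError("window radius must be >= 1 pixel")
        if not self.R > 0:
            raise CcFlowError("R must be positive")


@dataclass(frozen=True)
class CcSlabSpec:
    """CC slab geometry below the RPE-fit floor (device: 29 um offset,
    20 um thickness)."""

    offset_below_rpe_fit_um: float = 29.0
    thickness_um: float = 20.0

    def __post_init__(self):
        if not (self.offset_below_rpe_fit_um > 0 and self.thickness_um > 0):
            raise CcFlowError("slab offset and thickness must be positive")


@dataclass(frozen=True)
class FdMetrics:
    fd_percent: float
    fd_mean_size_um2: float   # NaN when no deficits remain
    fd_count: int
    region_label: str = ""


def extract_cc_slab(volume: OctVolume, rpe_floor: Surface,
                    spec: CcSlabSpec = CcSlabSpec()) -> Raster:
    """Mean-intensity en-face slab below the RPE-fit floor.

    Phantom-grade stand-in for the device's OCTA decorrelation slab; when
    en-face flow/structure pairs are supplied directly (the normal phantom
    path) this is bypassed.
    """
    if rpe_floor.shape != volume.lateral_shape:
        raise CcFlowError("floor surface and volume grids differ")
    ap = volume.axial_pitch_um
    top_um = rpe_floor.z_um + spec.offset_below_rpe_fit_um
    n_vox = max(1, int(round(spec.thickness_um / ap)))
    z0 = np.rint(top_um / ap).astype(int)
    if np.any(z0 < 0) or np.any(z0 + n_vox > volume.values.shape[0]):
        raise CcFlowError("CC slab exits the volume")
    idx = z0[None, :, :] + np.arange(n_vox)[:, None, None]
    slab_vals = np.take_along_axis(volume.values, idx, axis=0)
    return Raster(slab_vals.mean(axis=0), volume.lateral_pitch_um)


def compensate_flow(flow: Raster, structure: Raster,
                    floor_fraction: float = 0.1,
                    smooth_sigma_px: float = 3.0,
                    roi: np.ndarray | None = None) -> Raster:
    """Undo shadowing by scaling flow with the inverse smoothed structure.

    compensated = flow * S_ref / max(S_smooth, eps * S_ref) with S_smooth an
    isotropically smoothed structure raster and S_ref its ROI median. Gain
    is capped at 1/eps where the structure falls below the floor, and the
    output is clipped to the input dynamic range.
    """
    if flow.shape != structure.shape:
        raise CcFlowError("flow and structure rasters must share a grid")
    if not 0 < floor_fraction < 1:
        raise CcFlowError("floor_fraction must be in (0, 1)")
    s = structure.values.astype(float)
    if not np.any(s > 0):
        raise CcFlowError("structure image is identically zero")
    s_smooth = ndimage.gaussian_filter(s, sigma=smooth_sigma_px,
                                       mode="nearest")
    sel = np.asarray(roi, dtype=bool) if roi is not None else np.ones_like(
        s, dtype=bool)
    s_ref = float(np.median(s_smooth[sel]))
    if s_ref <= 0:
        raise CcFlowError("structure reference level is zero inside the ROI")
    gain = s_ref / np.maximum(s_smooth, floor_fraction * s_ref)
    comp = np.clip(flow.values * gain, flow.values.min(), flow.values.max())
    return Raster(comp, flow.lateral_pitch_um)


def remove_projection_artifacts(analysis_mask: np.ndarray,
                                vessel_mask: np.ndarray | None) -> np.ndarray:
    """Exclude retinal-vessel projection pixels from the analyzed area.

    Vessel pixels are treated as not-analyzed (neither flow nor deficit);
    an empty/absent mask is a no-op.
    """
    analysis_mask = np.asarray(analysis_mask, dtype=bool)
    if vessel_mask is None:
        return analysis_mask
    vessel_mask = np.asarray(vessel_mask, dtype=bool)
    if vessel_mask.shape != analysis_mask.shape:
        raise CcFlowError("vessel mask must share the analysis grid")
    return analysis_mask & ~vessel_mask


def _normalize_unit(values: np.ndarray) -> np.ndarray:
    """Map image intensities onto [0, 1] for the Phansalkar formula."""
    if np.issubdtype(values.dtype, np.integer):
        return values.astype(float) / float(np.iinfo(values.dtype).max)
    v = values.astype(float)
    if v.min() >= 0.0 and v.max() <= 1.0:
        return v
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        raise CcFlowError(
            "constant float image outside [0,1] cannot be normalized")
    return (v - lo) / (hi - lo)


def phansalkar_binarize(image: Raster | np.ndarray,
                        params: PhansalkarParams = PhansalkarParams()
                        ) -> np.ndarray:
    """Phansalkar local threshold; returns the boolean deficit mask.

    Per pixel, over the circular window of the given radius, the local mean
    m and SD s define T = m * (1 + p*exp(-q*m) + k*(s/R - 1)); a pixel is a
    flow deficit iff its value <= T. Windows are truncated at image borders
    (statistics use in-bounds pixels only, never padded values).
    """
    vals = image.values if isinstance(image, Raster) else np.asarray(image)
    v = _normalize_unit(vals)
    r = params.window_radius_px
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    footprint = (yy * yy + xx * xx <= r * r).astype(float)
    ones = np.ones_like(v)
    count = ndimage.correlate(ones, footprint, mode="constant", cval=0.0)
    s1 = ndimage.correlate(v, footprint, mode="constant", cval=0.0)
    s2 = ndimage.correlate(v * v, footprint, mode="constant", cval=0.0)
    m = s1 / count
    var = np.maximum(s2 / count - m * m, 0.0)
    s = np.sqrt(var)
    T = m * (1.0 + params.p * np.exp(-params.q * m)
             + params.k * (s / params.R - 1.0))
    return v <= T


def remove_small_deficits(deficits: np.ndarray, lateral_pitch_um: float,
                          min_equiv_diameter_um: float = 24.0) -> np.ndarray:
    """Clear connected components (8-connectivity) whose equivalent
    diameter 2*sqrt(area/pi) is strictly below the cutoff."""
    deficits = np.asarray(deficits, dtype=bool)
    labels, n = measure.label(deficits, connectivity=2, return_num=True)
    if n == 0:
        return deficits.copy()
    areas_px = np.bincount(labels.ravel())[1:]
    diam = equiv_diameter_um(areas_px * lateral_pitch_um ** 2)
    keep = np.concatenate([[False], diam >= min_equiv_diameter_um])
    return keep[labels]


def fd_metrics(deficits: np.ndarray, analysis_mask: np.ndarray,
               lateral_pitch_um: float, region_label: str = "") -> FdMetrics:
    """FD%, mean deficit size (um^2) and count within an analysis mask.

    Components are labeled on the full deficit raster but measured by their
    in-mask area, which keeps FD% exactly area-additive across a partition
    of the mask.
    """
    deficits = np.asarray(deficits, dtype=bool)
    analysis_mask = np.asarray(analysis_mask, dtype=bool)
    if deficits.shape != analysis_mask.shape:
        raise CcFlowError("deficit and analysis masks must share a grid")
    if not analysis_mask.any():
        raise CcFlowError("empty analysis mask")
    inside = deficits & analysis_mask
    fd_percent = 100.0 * inside.sum() / analysis_mask.sum()
    labels = measure.label(deficits, connectivity=2)
    in_mask_areas = np.bincount(labels[analysis_mask].ravel(),
                                minlength=labels.max() + 1)[1:]
    in_mask_areas = in_mask_areas[in_mask_areas > 0]
    count = int(in_mask_areas.size)
    mean_size = (float(in_mask_areas.mean()) * lateral_pitch_um ** 2
                 if count else float("nan"))
    return FdMetrics(fd_percent=float(fd_percent),
                     fd_mean_size_um2=mean_size,
                     fd_count=count, region_label=region_label)
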