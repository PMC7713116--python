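"""Ellipsoid-zone (EZ) en-face slab extraction and normalized reflectivity.

The EZ en-face image is the mean intensity over a 21 um slab whose inner
boundary sits 45 um above (toward the vitreous from) the RPE surface,
following its contour. Reflectivity is normalized per eye with a dark
(vitreous) and bright (RNFL) reference:

    norm = (mu_EZ - mu_vitreous) / (mu_RNFL - mu_vitreous)

which makes the readout invariant to global gain/offset changes of the
scan — the device brightness depends on uncontrollable acquisition factors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import OctVolume, Raster, RegionMasks, Surface


class EzError(ValueError):
    pass


@dataclass(frozen=True)
class SlabSpec:
    """EZ slab geometry: inner boundary ``offset_above_rpe_um`` above the
    RPE, thickness ``thickness_um`` (device defaults 45 / 21 um)."""

    offset_above_rpe_um: float = 45.0
    thickness_um: float = 21.0

    def __post_init__(self):
        if not (self.offset_above_rpe_um > 0 and self.thickness_um > 0):
            raise EzError("slab offset and thickness must be positive")


@dataclass(frozen=True)
class EzResult:
    normalized_whole_roi: float
    normalized_drusen_free: float
    normalized_drusen: float          # NaN when the region is empty/missing
    raw_means: tuple                  # (mu_ez_whole, mu_vitreous, mu_rnfl)


def extract_ez_enface(volume: OctVolume, rpe: Surface,
                      slab: SlabSpec = SlabSpec(),
                      max_clipped_fraction: float = 0.01) -> Raster:
    """Mean-intensity en-face projection of the EZ slab.

    For each A-scan the axial window is
    ``[rpe_z - offset, rpe_z - offset + thickness]`` (toward the vitreous
    from the RPE). The slab must stay inside the volume on all but
    ``max_clipped_fraction`` of A-scans.
    """
    if rpe.shape != volume.lateral_shape:
        raise EzError("RPE surface and volume grids differ")
    ap = volume.axial_pitch_um
    top_um = rpe.z_um - slab.offset_above_rpe_um
    n_vox = max(1, int(round(slab.thickness_um / ap)))
    z0 = np.rint(top_um / ap).astype(int)
    out_of_volume = (z0 < 0) | (z0 + n_vox > volume.values.shape[0])
    if out_of_volume.mean() > max_clipped_fraction:
        raise EzError(
            f"EZ slab exits the volume on {100 * out_of_volume.mean():.1f}% "
            "of A-scans")
    z0 = np.clip(z0, 0, volume.values.shape[0] - n_vox)
    idx = z0[None, :, :] + np.arange(n_vox)[:, None, None]
    slab_vals = np.take_along_axis(volume.values, idx, axis=0)
    return Raster(slab_vals.mean(axis=0), volume.lateral_pitch_um)


def sample_reference(volume: OctVolume, mask, which: str = "",
                     z_range_um: tuple[float, float] | None = None) -> float:
    """Arithmetic mean intensity over a reference region.

    ``mask`` is either a 3-D boolean region of the volume, or a 2-D lateral
    mask combined with an axial window ``z_range_um = (z_lo, z_hi)`` (um,
    half-open on the top of the volume side).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim == 3:
        if mask.shape != volume.values.shape:
            raise EzError("3-D reference mask must match the volume")
        sel = mask
    elif mask.ndim == 2:
        if z_range_um is None:
            raise EzError("a lateral reference mask needs a z_range_um")
        if mask.shape != volume.lateral_shape:
            raise EzError("lateral reference mask must match the grid")
        z = np.arange(volume.values.shape[0]) * volume.axial_pitch_um
        band = (z >= z_range_um[0]) & (z < z_range_um[1])
        sel = band[:, None, None] & mask[None, :, :]
    else:
        raise EzError("reference mask must be 2-D or 3-D")
    if not sel.any():
        raise EzError(f"empty {which or 'reference'} region")
    return float(volume.values[sel].mean())


def normalize_reflectivity(mu_ez: float, mu_vitreous: float,
                           mu_rnfl: float) -> float:
    """Two-point linear rescaling between the dark and bright references.

    Not clipped: values outside [0, 1] are legal for extreme inputs.
    """
    if not mu_rnfl > mu_vitreous:
        raise EzError("references inverted (RNFL must be brighter than "
                      "vitreous); invalid scan")
    return (mu_ez - mu_vitreous) / (mu_rnfl - mu_vitreous)


def regional_reflectivity(enface: Raster, masks: RegionMasks,
                          mu_vitreous: float, mu_rnfl: float) -> EzResult:
    """Normalized EZ reflectivity in the whole ROI and per sub-region.

    Major-retinal-vessel pixels are excluded from every regional mean; a
    region emptied by vessel exclusion is reported as NaN with a warning.
    """
    if masks.roi.shape != enface.shape:
        raise EzError("masks and en-face image must share a grid")
    if not masks.roi.any():
        raise EzError("empty ROI")
    vals = enface.values

    def region_norm(region: np.ndarray) -> tuple[float, float]:
        sel = region & ~masks.vessel_excluded
        if not sel.any():
            return float("nan"), float("nan")
        mu = float(vals[sel].mean())
        return normalize_reflectivity(mu, mu_vitreous, mu_rnfl), mu

    norm_roi, mu_roi = region_norm(masks.roi)
    norm_free, _ = region_norm(masks.drusen_free)
    norm_drus, _ = region_norm(masks.drusen)
    if np.isnan(norm_roi) or np.isnan(norm_free):
        warnings.warn("vessel exclusion emptied an analysis region",
                      stacklevel=2)
    return EzResult(normalized_whole_roi=norm_roi,
                    normalized_drusen_free=norm_free,
                    normalized_drusen=norm_drus,
                    raw_means=(mu_roi, mu_vitreous, mu_rnfl))
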