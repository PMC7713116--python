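"""File I/O: TIFF/PNG rasters and volumes, truth sidecars, cohort CSV."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .geometry import OctVolume, Raster

ELEVATION_FIXED_POINT = 10.0  # 16-bit elevation TIFFs store um x 10


def save_raster(path, raster: Raster) -> None:
    """Write an en-face raster as 16-bit TIFF (intensities rounded)."""
    path = Path(path)
    data = np.clip(np.round(raster.values), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data, resolution=(
        10_000.0 / raster.lateral_pitch_um,) * 2)


def load_raster(path, lateral_pitch_um: float) -> Raster:
    return Raster(tifffile.imread(path).astype(float), lateral_pitch_um)


def save_volume(path, volume: OctVolume) -> None:
    """Write a structural volume as a multi-page TIFF (one page per depth)."""
    data = np.clip(np.round(volume.values), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data)


def load_volume(path, axial_pitch_um: float,
                lateral_pitch_um: float) -> OctVolume:
    return OctVolume(tifffile.imread(path).astype(float),
                     axial_pitch_um=axial_pitch_um,
                     lateral_pitch_um=lateral_pitch_um)


def save_mask_png(path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))


def load_mask_png(path) -> np.ndarray:
    return np.asarray(iio.imread(path)) > 0


def save_elevation_tiff(path, elevation_um: np.ndarray) -> None:
    """Elevation map as 16-bit TIFF in fixed-point um x 10."""
    data = np.clip(np.round(np.asarray(elevation_um) * ELEVATION_FIXED_POINT),
                   0, 65535).astype(np.uint16)
    tifffile.imwrite(Path(path), data)


def load_elevation_tiff(path) -> np.ndarray:
    return tifffile.imread(path).astype(float) / ELEVATION_FIXED_POINT


def save_truth_sidecar(path, scalars: dict) -> None:
    """JSON sidecar of scalar truth values for a phantom."""
    Path(path).write_text(json.dumps(scalars, indent=2, sort_keys=True))


def records_to_frame(records) -> pd.DataFrame:
    from dataclasses import asdict
    return pd.DataFrame([asdict(r) for r in records])
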