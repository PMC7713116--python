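"""Seeded synthetic OCT/OCTA phantoms with planted ground truth.

The phantom emulates the statistical structure the analysis assumes — a
layered macular OCT volume (vitreous, RNFL, inner layers, EZ band, RPE,
choroid) over a smooth Bruch's-membrane floor, dome-shaped drusen that
elevate the RPE and cast shadows on deeper signal, a spatial EZ attenuation
field, multiplicative gamma speckle, and paired CC en-face flow/structure
rasters with planted dark flow-deficit blobs — so every pipeline stage can
be verified against construction-time truth without patient data.

It makes no attempt at physically realistic wave optics; noise and shadow
magnitudes are calibration knobs of the phantom, not claims about device
physics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .geometry import OctVolume, Raster, Surface


class PhantomError(ValueError):
    pass


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LayerSpec:
    name: str
    mean_intensity: float
    thickness_um: float


#: Layer stack ordered vitreous -> RPE. The EZ band is anchored to the RPE
#: surface (24 um outer-segment gap below it); vitreous/RNFL anchor at the
#: top of the volume; inner layers fill the remainder.
DEFAULT_LAYERS = (
    LayerSpec("vitreous", 4.0, 120.0),
    LayerSpec("rnfl", 180.0, 40.0),
    LayerSpec("inner", 80.0, 160.0),
    LayerSpec("ez", 200.0, 32.0),
    LayerSpec("rpe", 240.0, 25.0),
)

OS_GAP_UM = 24.0          # EZ-band bottom to RPE surface
OS_GAP_INTENSITY = 30.0
CHOROID_INTENSITY = 55.0


@dataclass(frozen=True)
class DomeSpec:
    """One druse: plateau-cored dome with a raised-cosine taper.

    ``center_row_um/center_col_um`` are physical coordinates from the
    top-left pixel center, so one drusen set renders consistently on grids
    of different pitch. Peak heights are capped at 150 um.
    """

    center_row_um: float
    center_col_um: float
    radius_um: float
    peak_um: float


@dataclass(frozen=True)
class PhantomConfig:
    grid_rows: int = 500
    grid_cols: int = 500
    lateral_pitch_um: float = 12.0          # 6 mm / 500 px
    depth_voxels: int = 160
    axial_pitch_um: float = 5.0
    layers: tuple = DEFAULT_LAYERS
    drusen_spec: tuple = ()
    dome_taper_fraction: float = 0.10       # taper annulus / dome radius
    ez_attenuation_field: object = None     # scalar or (rows, cols) in (0,1]
    shadow_factor: float = 1.0              # multiplicative, under drusen
    fd_fraction: float = 0.0
    fd_blob_scale_um: float = 36.0          # characteristic deficit diameter
    speckle_shape: float = 10.0             # gamma shape; None/inf = off
    cc_speckle_shape: float = 40.0          # CC rasters emulate averaged scans
    cc_background_flow: float = 210.0
    cc_background_structure: float = 180.0
    cc_deficit_contrast: float = 0.12       # blob level / background level
    cc_noise_floor: float = 12.0            # additive, unshadowed
    psf_sigma_um: float = 6.0               # lateral PSF (14 um FWHM)
    bm_tilt_um: tuple = (8.0, 5.0)          # Bruch floor tilt across the FOV
    seed: int = 0

    def __post_init__(self):
        if self.grid_rows < 2 or self.grid_cols < 2:
            raise PhantomError("grid must have at least 2x2 pixels")
        if not (self.lateral_pitch_um > 0 and self.axial_pitch_um > 0):
            raise PhantomError("pitches must be positive")
        if not 0.0 <= self.fd_fraction < 1.0:
            raise PhantomError("fd_fraction must lie in [0, 1)")
        if self.fd_blob_scale_um < 24.0:
            raise PhantomError("fd_blob_scale_um must be >= 24 um")
        if not 0.0 < self.shadow_factor <= 1.0:
            raise PhantomError("shadow_factor must lie in (0, 1]")
        for d in self.drusen_spec:
            if d.peak_um < 0 or d.peak_um > 150:
                raise PhantomError("drusen peak heights must be in [0, 150] um")
            if d.radius_um <= 0:
                raise PhantomError("drusen radii must be positive")
        att = self.ez_attenuation_field
        if att is not None:
            a = np.asarray(att, dtype=float)
            if np.any(a <= 0) or np.any(a > 1):
                raise PhantomError("EZ attenuation must lie in (0, 1]")
        for shape in (self.speckle_shape, self.cc_speckle_shape):
            if shape is not None and not shape > 0:
                raise PhantomError("speckle shape must be positive (or None)")
        if self.z_rpe_nominal_um() + self._layer("rpe").thickness_um \
                > (self.depth_voxels - 1) * self.axial_pitch_um:
            raise PhantomError("layer stack exceeds the volume depth extent")

    def _layer(self, name: str) -> LayerSpec:
        for lay in self.layers:
            if lay.name == name:
                return lay
        raise PhantomError(f"missing layer {name!r}")

    def z_rpe_nominal_um(self) -> float:
        """Nominal (drusen-free, untilted) RPE depth from the top."""
        t = sum(self._layer(n).thickness_um
                for n in ("vitreous", "rnfl", "inner", "ez"))
        return t + OS_GAP_UM

    def headroom_um(self) -> float:
        """Maximum drusen elevation before the EZ band hits the RNFL."""
        top = (self._layer("vitreous").thickness_um
               + self._layer("rnfl").thickness_um)
        ez_span = self._layer("ez").thickness_um + OS_GAP_UM
        return self.z_rpe_nominal_um() - top - ez_span


@dataclass
class ReferenceRegions:
    """Lateral masks + axial windows of the dark/bright reference bands."""

    vitreous_mask: np.ndarray
    vitreous_z_um: tuple
    rnfl_mask: np.ndarray
    rnfl_z_um: tuple


@dataclass
class PhantomTruth:
    """Construction-time ground truth (never measured from the images)."""

    true_drusen_mask: np.ndarray          # half-peak dome footprints
    true_elevation: np.ndarray            # um
    true_fd_mask: np.ndarray | None
    true_fd_fraction: float
    true_ez_attenuation: np.ndarray
    true_rpe_surface: Surface | None
    true_bm_surface: Surface | None
    reference_masks: ReferenceRegions | None


# ---------------------------------------------------------------------------
# analytic fields
# ---------------------------------------------------------------------------

def _dome_profile(dist_um, radius_um, peak_um, taper_fraction):
    """Plateau-cored dome: flat at ``peak_um`` out to (1-taper)*R, then a
    raised-cosine taper to zero at R. Smooth, bounded, analytic peak."""
    r0 = (1.0 - taper_fraction) * radius_um
    taper = max(radius_um - r0, 1e-9)
    h = np.zeros_like(dist_um)
    h[dist_um <= r0] = peak_um
    ramp = (dist_um > r0) & (dist_um < radius_um)
    h[ramp] = 0.5 * peak_um * (
        1.0 + np.cos(math.pi * (dist_um[ramp] - r0) / taper))
    return h


def elevation_field(config: PhantomConfig, shape: tuple[int, int],
                    pitch_um: float) -> np.ndarray:
    """True RPE elevation (um) of the configured drusen on any pixel grid.

    Overlapping domes combine by maximum so the peak of every dome is exact.
    """
    elev = np.zeros(shape)
    rr = np.arange(shape[0])[:, None] * pitch_um
    cc = np.arange(shape[1])[None, :] * pitch_um
    for d in config.drusen_spec:
        dist = np.hypot(rr - d.center_row_um, cc - d.center_col_um)
        np.maximum(elev, _dome_profile(dist, d.radius_um, d.peak_um,
                                       config.dome_taper_fraction), out=elev)
    return elev


def drusen_truth_mask(config: PhantomConfig, shape: tuple[int, int],
                      pitch_um: float) -> np.ndarray:
    """Half-peak footprint of the planted domes (the recovery oracle)."""
    mask = np.zeros(shape, dtype=bool)
    rr = np.arange(shape[0])[:, None] * pitch_um
    cc = np.arange(shape[1])[None, :] * pitch_um
    for d in config.drusen_spec:
        if d.peak_um <= 0:
            continue
        r_half = (1.0 - 0.5 * config.dome_taper_fraction) * d.radius_um
        dist = np.hypot(rr - d.center_row_um, cc - d.center_col_um)
        mask |= dist <= r_half
    return mask


def _bm_surface(config: PhantomConfig, shape: tuple[int, int]) -> np.ndarray:
    """Smooth (tilted-plane) Bruch's-membrane depth field in um."""
    tr, tc = config.bm_tilt_um
    r = np.linspace(0.0, 1.0, shape[0])[:, None]
    c = np.linspace(0.0, 1.0, shape[1])[None, :]
    return config.z_rpe_nominal_um() + tr * (r - 0.5) + tc * (c - 0.5)


def _attenuation_field(config: PhantomConfig,
                       shape: tuple[int, int]) -> np.ndarray:
    att = config.ez_attenuation_field
    if att is None:
        return np.ones(shape)
    a = np.asarray(att, dtype=float)
    if a.ndim == 0:
        return np.full(shape, float(a))
    if a.shape != shape:
        raise PhantomError("EZ attenuation field shape mismatch")
    return a.copy()


def _speckle(rng: np.random.Generator, shape_param, size) -> np.ndarray:
    """Unit-mean multiplicative gamma speckle; None/inf disables it."""
    if shape_param is None or not np.isfinite(shape_param):
        return np.ones(size, dtype=np.float32)
    return rng.gamma(shape_param, 1.0 / shape_param,
                     size=size).astype(np.float32)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_volume(config: PhantomConfig) -> tuple[OctVolume, PhantomTruth]:
    """Layered structural volume with drusen, EZ attenuation and speckle.

    Identical (config, seed) pairs produce bit-identical volumes.
    """
    shape = (config.grid_rows, config.grid_cols)
    pitch = config.lateral_pitch_um
    elev = elevation_field(config, shape, pitch)
    if elev.max() > config.headroom_um():
        raise PhantomError(
            f"drusen of {elev.max():.0f} um do not fit: the EZ band would "
            "enter the RNFL; increase the inner-layer thickness")

    z_bm = _bm_surface(config, shape)
    z_rpe = z_bm - elev
    att = _attenuation_field(config, shape)

    lay = {l.name: l for l in config.layers}
    t_v = lay["vitreous"].thickness_um
    t_r = lay["rnfl"].thickness_um
    t_ez = lay["ez"].thickness_um
    t_rpe = lay["rpe"].thickness_um

    depth = config.depth_voxels
    ap = config.axial_pitch_um
    z = (np.arange(depth, dtype=np.float32) * ap)[:, None, None]
    z_rpe3 = z_rpe[None, :, :].astype(np.float32)

    # Anti-aliased voxelization: each voxel integrates the layer stack over
    # its axial extent, so boundary voxels carry partial-volume mixtures and
    # sub-voxel surface positions are encoded in the data (as the finite
    # axial PSF does in a real scan). The RPE band is symmetric about the
    # surface: the depth-reflectivity peak of the band is the planted RPE
    # reference.
    big = np.float32(1e9)
    ez_val = (lay["ez"].mean_intensity * att[None, :, :]).astype(np.float32)
    stack = (
        (-big, np.float32(t_v), np.float32(lay["vitreous"].mean_intensity)),
        (np.float32(t_v), np.float32(t_v + t_r),
         np.float32(lay["rnfl"].mean_intensity)),
        (np.float32(t_v + t_r), z_rpe3 - (t_ez + OS_GAP_UM),
         np.float32(lay["inner"].mean_intensity)),
        (z_rpe3 - (t_ez + OS_GAP_UM), z_rpe3 - OS_GAP_UM, ez_val),
        (z_rpe3 - OS_GAP_UM, z_rpe3 - t_rpe / 2.0,
         np.float32(OS_GAP_INTENSITY)),
        (z_rpe3 - t_rpe / 2.0, z_rpe3 + t_rpe / 2.0,
         np.float32(lay["rpe"].mean_intensity)),
        (z_rpe3 + t_rpe / 2.0, big, np.float32(CHOROID_INTENSITY)),
    )
    half = np.float32(ap / 2.0)
    vol = np.zeros((depth,) + shape, dtype=np.float32)
    for top, bot, inten in stack:
        cov = np.clip(np.minimum(bot, z + half) - np.maximum(top, z - half),
                      0.0, ap) / np.float32(ap)
        vol += cov * inten

    if config.shadow_factor < 1.0 and elev.max() > 0:
        sh = 1.0 - (1.0 - config.shadow_factor) * (elev > 0)
        below = z >= z_rpe3
        vol *= np.where(below, sh[None, :, :], 1.0).astype(np.float32)

    rng = np.random.default_rng([config.seed, 1])
    vol *= _speckle(rng, config.speckle_shape, vol.shape)

    refs = ReferenceRegions(
        vitreous_mask=np.ones(shape, dtype=bool),
        vitreous_z_um=(0.0, max(t_v - 10.0, config.axial_pitch_um)),
        rnfl_mask=(np.arange(shape[0])[:, None] < shape[0] // 4)
        & np.ones((1, shape[1]), dtype=bool),
        rnfl_z_um=(t_v + 5.0, t_v + t_r - 5.0),
    )
    truth = PhantomTruth(
        true_drusen_mask=drusen_truth_mask(config, shape, pitch),
        true_elevation=elev,
        true_fd_mask=None,
        true_fd_fraction=float("nan"),
        true_ez_attenuation=att,
        true_rpe_surface=Surface(z_rpe),
        true_bm_surface=Surface(z_bm),
        reference_masks=refs,
    )
    volume = OctVolume(vol, axial_pitch_um=config.axial_pitch_um,
                       lateral_pitch_um=pitch)
    return volume, truth


def _plant_fd_blobs(config: PhantomConfig,
                    rng: np.random.Generator) -> np.ndarray:
    """Random disks, wholly inside the grid, painted until the target area
    fraction is reached. The recorded fraction, not the target, is truth."""
    shape = (config.grid_rows, config.grid_cols)
    mask = np.zeros(shape, dtype=bool)
    if config.fd_fraction == 0.0:
        return mask
    pitch = config.lateral_pitch_um
    target_px = config.fd_fraction * mask.size
    painted = 0
    max_tries = 100_000
    for _ in range(max_tries):
        if painted >= target_px:
            break
        diam_um = config.fd_blob_scale_um * rng.uniform(0.8, 1.8)
        r_px = max(diam_um / 2.0 / pitch, 1.0)
        lo, hi_r, hi_c = r_px, shape[0] - 1 - r_px, shape[1] - 1 - r_px
        if hi_r <= lo or hi_c <= lo:
            raise PhantomError("grid too small for the deficit blob scale")
        cr = rng.uniform(lo, hi_r)
        cc = rng.uniform(lo, hi_c)
        r0, r1 = int(cr - r_px), min(int(cr + r_px) + 2, shape[0])
        c0, c1 = int(cc - r_px), min(int(cc + r_px) + 2, shape[1])
        sub = mask[r0:r1, c0:c1]
        rr = np.arange(r0, r1)[:, None] - cr
        ccx = np.arange(c0, c1)[None, :] - cc
        disk = rr * rr + ccx * ccx <= r_px * r_px
        painted += int((disk & ~sub).sum())
        sub |= disk
    else:
        raise PhantomError("failed to reach the target deficit fraction")
    return mask


def generate_cc_pair(config: PhantomConfig
                     ) -> tuple[Raster, Raster, PhantomTruth]:
    """Paired CC en-face flow/structure rasters with planted deficits.

    The flow raster is a bright background with planted dark blobs covering
    ~``fd_fraction`` of the area; both rasters are attenuated by
    ``shadow_factor`` under the drusen footprint, carry multiplicative
    speckle plus an additive (unshadowed) noise floor, and are blurred by
    the lateral PSF. The structure raster carries the shadow but not the
    deficits.
    """
    shape = (config.grid_rows, config.grid_cols)
    pitch = config.lateral_pitch_um
    rng_blob = np.random.default_rng([config.seed, 2])
    rng_noise = np.random.default_rng([config.seed, 3])

    fd_mask = _plant_fd_blobs(config, rng_blob)
    elev = elevation_field(config, shape, pitch)
    shadow = 1.0 - (1.0 - config.shadow_factor) * (elev > 0)

    flow_sig = config.cc_background_flow * (
        1.0 - (1.0 - config.cc_deficit_contrast) * fd_mask)
    struct_sig = np.full(shape, config.cc_background_structure)

    def render(signal):
        img = (signal * shadow
               * _speckle(rng_noise, config.cc_speckle_shape, shape)
               + config.cc_noise_floor
               * _speckle(rng_noise, config.cc_speckle_shape, shape))
        sigma = config.psf_sigma_um / pitch
        return np.clip(ndimage.gaussian_filter(img, sigma, mode="nearest"),
                       0.0, None)

    flow = Raster(render(flow_sig), pitch)
    structure = Raster(render(struct_sig), pitch)
    truth = PhantomTruth(
        true_drusen_mask=drusen_truth_mask(config, shape, pitch),
        true_elevation=elev,
        true_fd_mask=fd_mask,
        true_fd_fraction=float(fd_mask.mean()),
        true_ez_attenuation=_attenuation_field(config, shape),
        true_rpe_surface=None,
        true_bm_surface=None,
        reference_masks=None,
    )
    return flow, structure, truth


# ---------------------------------------------------------------------------
# cohort phantoms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupEffects:
    """Planted per-eye outcome distributions of one cohort arm.

    Defaults for the AMD and control arms mirror the reported cohort:
    EZ normalized reflectivity 0.76 +/- 0.10 vs 0.85 +/- 0.08, CC flow
    deficit fraction 0.241 +/- 0.053 vs 0.192 +/- 0.062, and (AMD only) a
    planted rank coupling between EZ attenuation and deficit fraction.
    """

    ez_norm_mean: float
    ez_norm_sd: float
    fd_fraction_mean: float
    fd_fraction_sd: float
    rho_ez_fd: float = 0.0
    n_drusen_range: tuple = (0, 0)
    drusen_peak_range_um: tuple = (30.0, 100.0)
    drusen_radius_range_um: tuple = (150.0, 400.0)
    drusen_extra_attenuation: float = 0.9   # extra EZ factor under drusen

    def __post_init__(self):
        if self.ez_norm_sd < 0 or self.fd_fraction_sd < 0:
            raise PhantomError("group-effect SDs must be non-negative")
        if not -1.0 <= self.rho_ez_fd <= 1.0:
            raise PhantomError("target rank coupling must lie in [-1, 1]")


AMD_EFFECTS = GroupEffects(ez_norm_mean=0.76, ez_norm_sd=0.10,
                           fd_fraction_mean=0.241, fd_fraction_sd=0.053,
                           rho_ez_fd=-0.4, n_drusen_range=(4, 10))
CONTROL_EFFECTS = GroupEffects(ez_norm_mean=0.85, ez_norm_sd=0.08,
                               fd_fraction_mean=0.192, fd_fraction_sd=0.062)


@dataclass
class CohortEye:
    """Lazy per-eye phantom: configs plus planted scalar truth."""

    eye_id: str
    group: str
    volume_config: PhantomConfig
    cc_config: PhantomConfig
    planted_ez_norm: float
    planted_fd_fraction: float


def coupled_ranks(n: int, rho_target: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Permutation ``pi`` with Spearman corr(i, pi(i)) close to the target.

    Normal scores exactly correlated at the Pearson level implied by the
    Gaussian-copula map r = 2 sin(pi * rho / 6) are built first
    (Iman-Conover style), then refined by greedy pair swaps until the
    realized Spearman of the permutation is within 0.02 of the target, so
    the planted coupling is a construction, not a draw.
    """
    ranks1 = np.arange(n, dtype=float)
    if n < 3 or rho_target == 0.0:
        return rng.permutation(n)
    r = 2.0 * math.sin(math.pi * rho_target / 6.0)
    s1 = (ranks1 - ranks1.mean()) / ranks1.std()
    e = rng.standard_normal(n)
    e -= e.mean()
    e -= s1 * (e @ s1) / (s1 @ s1)
    if np.allclose(e, 0):
        e = np.roll(s1, 1)
    e /= np.sqrt((e @ e) / n)
    s2 = r * s1 + math.sqrt(max(1.0 - r * r, 0.0)) * e
    perm = np.argsort(np.argsort(s2))

    def rho_of(p):
        return float(np.corrcoef(ranks1, p)[0, 1])

    rho = rho_of(perm)
    for _ in range(20 * n):
        if abs(rho - rho_target) <= 0.02:
            break
        i, j = rng.integers(0, n, size=2)
        if i == j:
            continue
        cand = perm.copy()
        cand[i], cand[j] = cand[j], cand[i]
        rho_c = rho_of(cand)
        if abs(rho_c - rho_target) < abs(rho - rho_target):
            perm, rho = cand, rho_c
    return perm


#: Down-scaled per-eye problem sizes used for cohort simulation: a coarse
#: structural volume (the EZ/drusen path) and a finer CC raster grid.
COHORT_VOLUME_TEMPLATE = PhantomConfig(grid_rows=120, grid_cols=120,
                                       lateral_pitch_um=50.0,
                                       depth_voxels=120, axial_pitch_um=5.0)
COHORT_CC_TEMPLATE = PhantomConfig(grid_rows=400, grid_cols=400,
                                   lateral_pitch_um=15.0)


def attenuation_for_target(config: PhantomConfig, target_norm: float) -> float:
    """EZ attenuation value that plants a given normalized reflectivity,
    inverting the dark/bright two-point normalization against the
    configured layer means."""
    mu_v = config._layer("vitreous").mean_intensity
    mu_r = config._layer("rnfl").mean_intensity
    mu_e = config._layer("ez").mean_intensity
    att = (mu_v + target_norm * (mu_r - mu_v)) / mu_e
    if not 0.0 < att <= 1.0:
        raise PhantomError(
            f"target normalized reflectivity {target_norm:.3f} is outside "
            "the range the configured layer means can plant")
    return att


def generate_cohort(n_per_group: int,
                    amd_effects: GroupEffects = AMD_EFFECTS,
                    control_effects: GroupEffects = CONTROL_EFFECTS,
                    seed: int = 0,
                    volume_template: PhantomConfig = COHORT_VOLUME_TEMPLATE,
                    cc_template: PhantomConfig = COHORT_CC_TEMPLATE,
                    ) -> list[CohortEye]:
    """Two arms of per-eye phantom specs with planted outcome values.

    Per-eye EZ targets and deficit fractions are drawn from the arm's
    distributions (clipped to physically plantable ranges) and coupled at
    the arm's target Spearman rho via :func:`coupled_ranks`.
    """
    if n_per_group < 2:
        raise PhantomError("need at least 2 eyes per group")
    rng = np.random.default_rng([seed, 4])
    eyes: list[CohortEye] = []
    for group, eff in (("AMD", amd_effects), ("control", control_effects)):
        ez = np.clip(rng.normal(eff.ez_norm_mean, eff.ez_norm_sd,
                                n_per_group), 0.30, 1.05)
        fd = np.clip(rng.normal(eff.fd_fraction_mean, eff.fd_fraction_sd,
                                n_per_group), 0.03, 0.60)
        ez_sorted = np.sort(ez)
        fd_sorted = np.sort(fd)
        perm = coupled_ranks(n_per_group, eff.rho_ez_fd, rng)
        fd_coupled = fd_sorted[perm]
        for i in range(n_per_group):
            eye_seed = int(rng.integers(0, 2**31 - 1))
            target = float(ez_sorted[i])
            fdf = float(fd_coupled[i])
            drusen = _draw_drusen(eff, volume_template, rng)
            vol_cfg = replace(volume_template, seed=eye_seed,
                              drusen_spec=drusen)
            att = _cohort_attenuation(vol_cfg, target, eff)
            vol_cfg = replace(vol_cfg, ez_attenuation_field=att)
            cc_cfg = replace(cc_template, seed=eye_seed, drusen_spec=drusen,
                             fd_fraction=fdf,
                             shadow_factor=0.6 if drusen else 1.0)
            eyes.append(CohortEye(
                eye_id=f"{group}-{i:03d}", group=group,
                volume_config=vol_cfg, cc_config=cc_cfg,
                planted_ez_norm=target, planted_fd_fraction=fdf))
    return eyes


def _draw_drusen(eff: GroupEffects, template: PhantomConfig,
                 rng: np.random.Generator) -> tuple:
    lo, hi = eff.n_drusen_range
    n = int(rng.integers(lo, hi + 1)) if hi > 0 else 0
    if n == 0:
        return ()
    extent_r = (template.grid_rows - 1) * template.lateral_pitch_um
    extent_c = (template.grid_cols - 1) * template.lateral_pitch_um
    headroom = template.headroom_um()
    domes = []
    for _ in range(n):
        radius = rng.uniform(*eff.drusen_radius_range_um)
        peak = min(rng.uniform(*eff.drusen_peak_range_um), headroom)
        domes.append(DomeSpec(
            center_row_um=rng.uniform(radius, extent_r - radius),
            center_col_um=rng.uniform(radius, extent_c - radius),
            radius_um=radius, peak_um=peak))
    return tuple(domes)


def _cohort_attenuation(cfg: PhantomConfig, target_norm: float,
                        eff: GroupEffects) -> np.ndarray:
    base = attenuation_for_target(cfg, target_norm)
    field = np.full((cfg.grid_rows, cfg.grid_cols), base)
    if cfg.drusen_spec and eff.drusen_extra_attenuation < 1.0:
        foot = drusen_truth_mask(cfg, field.shape, cfg.lateral_pitch_um)
        field[foot] *= eff.drusen_extra_attenuation
    return field
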