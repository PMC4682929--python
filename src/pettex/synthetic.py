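"""Synthetic test-beds: a uniform FDG phantom and a two-subtype lung cohort.

The phantom is a water-filled cylinder with uniform tracer concentration.
Its only "texture" is reconstruction noise, emulated as Gaussian white noise
convolved with a Gaussian point-spread function — a smoothed random field
that reproduces the spatial correlation of reconstructed PET images without
simulating the reconstruction itself.

The cohort emulates non-small-cell lung cancer patients: each synthetic
patient volume holds a low-uptake body background, a liver block of noisy
uniform uptake serving as healthy reference tissue, and one lung tumor with
a multiplicative intra-tumor texture field.  Adenocarcinoma-like tumors are
smaller, cooler and milder in texture; squamous-like tumors are larger,
hotter, carry a stronger texture amplitude and a low-uptake core — so the
subtype difference is primarily a difference in the absolute scale of the
uptake pattern, which fixed-bound resampling sees and min-max resampling
normalizes away.  Voxel noise is proportional to the local mean before PSF
smoothing, mimicking the count-dependent noise of PET.  All generators are
deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .voi import VOIMask, metabolic_volume, sphere_voi
from .volumes import VolumeGrid, SUV

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and noise of the uniform cylinder phantom.

    Defaults: 20 cm high, 16 cm diameter cylinder on a 4 mm isotropic grid,
    uniform SUV 3 with 15% white noise smoothed by a 7 mm FWHM PSF.
    """

    cylinder_height_mm: float = 200.0
    cylinder_diameter_mm: float = 160.0
    voxel_mm: float = 4.0
    mean_suv: float = 3.0
    noise_sd_frac: float = 0.15
    psf_fwhm_mm: float = 7.0
    margin_vox: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cylinder_height_mm", "cylinder_diameter_mm", "voxel_mm", "mean_suv"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd_frac < 0 or self.psf_fwhm_mm < 0:
            raise ValueError("noise level and PSF width must be non-negative")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        nr = int(round(self.cylinder_diameter_mm / self.voxel_mm)) + 2 * self.margin_vox
        nz = int(round(self.cylinder_height_mm / self.voxel_mm)) + 2 * self.margin_vox
        return (nr, nr, nz)

    @property
    def center_voxel(self) -> tuple[int, int, int]:
        nx, ny, nz = self.grid_shape
        return (nx // 2, ny // 2, nz // 2)


def _cylinder_mask(spec: PhantomSpec) -> np.ndarray:
    nx, ny, nz = spec.grid_shape
    cx, cy, cz = spec.center_voxel
    x, y, z = np.ogrid[0:nx, 0:ny, 0:nz]
    r_vox = spec.cylinder_diameter_mm / (2.0 * spec.voxel_mm)
    h_vox = spec.cylinder_height_mm / (2.0 * spec.voxel_mm)
    return ((x - cx) ** 2 + (y - cy) ** 2 <= r_vox**2) & (np.abs(z - cz) <= h_vox)


def phantom_cylinder_mask(spec: PhantomSpec) -> VOIMask:
    """Interior of the phantom cylinder as a mask."""
    return VOIMask(_cylinder_mask(spec))


def simulate_phantom(spec: PhantomSpec) -> VolumeGrid:
    """Uniform cylinder + white noise, convolved with the Gaussian PSF.

    With ``noise_sd_frac = 0`` the interior is exactly uniform; with
    ``psf_fwhm_mm = 0`` the noise is voxelwise independent.  Negative values
    produced by the noise are clipped to zero (SUV is non-negative).
    """
    rng = np.random.default_rng(spec.seed)
    inside = _cylinder_mask(spec)
    field_ = np.zeros(spec.grid_shape, dtype=float)
    field_[inside] = spec.mean_suv
    if spec.noise_sd_frac > 0:
        noise = np.zeros_like(field_)
        noise[inside] = rng.normal(
            0.0, spec.noise_sd_frac * spec.mean_suv, size=int(inside.sum())
        )
        field_ = field_ + noise
    if spec.psf_fwhm_mm > 0:
        sigma = spec.psf_fwhm_mm * _FWHM_TO_SIGMA / spec.voxel_mm
        field_ = ndimage.gaussian_filter(field_, sigma)
    np.clip(field_, 0.0, None, out=field_)
    return VolumeGrid(field_, (spec.voxel_mm,) * 3, unit=SUV)


def default_sphere_centers(spec: PhantomSpec) -> list[tuple[int, int, int]]:
    """Five sphere positions: cylinder center plus two radial and two axial
    offsets, all clear of the wall for the largest (17-voxel) sphere."""
    cx, cy, cz = spec.center_voxel
    return [
        (cx, cy, cz),
        (cx + 8, cy, cz),
        (cx, cy + 8, cz),
        (cx, cy, cz + 12),
        (cx, cy, cz - 12),
    ]


@dataclass(frozen=True)
class CohortSpec:
    """Generator settings for the synthetic lung-cancer cohort.

    Sizes default to 28 adenocarcinoma-like and 13 squamous-like patients.
    Tumor radii and peak SUVs are drawn per subtype; squamous-like tumors
    are larger, hotter and more heterogeneous: their multiplicative texture
    field has a larger amplitude and they carry a low-uptake core of radius
    ``core_radius_frac`` times the tumor radius at ``core_suv_fraction``
    times the peak (probability ``core_prob``).  The texture field is
    clipped asymmetrically (``*_clip_sd``, in units of its sd): shallow cold
    dips keep the whole lesion above the segmentation threshold while tall
    sparse hot spots widen each tumor's own intensity range, which keeps
    min-max-resampled statistics of tumors comparable to those of reference
    tissue.  Per-patient draws of acquisition noise (fraction of local mean
    before PSF smoothing) and texture length scale emulate between-patient
    acquisition and biology differences.
    """

    n_adeno: int = 28
    n_squamous: int = 13
    adeno_radius_range_mm: tuple[float, float] = (10.0, 22.0)
    squamous_radius_range_mm: tuple[float, float] = (16.0, 30.0)
    adeno_peak_suv_range: tuple[float, float] = (5.0, 8.5)
    squamous_peak_suv_range: tuple[float, float] = (8.5, 15.0)
    core_prob: float = 1.0
    core_suv_fraction: float = 0.45
    core_radius_frac: float = 0.55
    adeno_texture_frac: float = 0.50
    squamous_texture_frac: float = 0.75
    texture_length_range_mm: tuple[float, float] = (8.0, 12.0)
    adeno_clip_sd: tuple[float, float] = (0.5, 3.0)
    squamous_clip_sd: tuple[float, float] = (0.5, 3.0)
    liver_mean_suv: float = 2.2
    body_suv: float = 0.5
    noise_sd_frac_range: tuple[float, float] = (0.25, 0.40)
    psf_fwhm_mm: float = 7.0
    voxel_mm: float = 4.0
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    delay_range_min: tuple[float, float] = (62.0, 88.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_adeno < 0 or self.n_squamous < 0:
            raise ValueError("group sizes must be non-negative")
        for lo, hi in (
            self.adeno_peak_suv_range,
            self.squamous_peak_suv_range,
            self.adeno_radius_range_mm,
            self.squamous_radius_range_mm,
        ):
            if lo <= 0 or hi < lo:
                raise ValueError("ranges must be positive and ordered")
        if not 0.0 <= self.core_prob <= 1.0:
            raise ValueError("core probability must lie in [0, 1]")


#: fixed anatomy on the default 64^3 grid (voxel indices)
_LIVER_CENTER = (32, 32, 18)
_LIVER_HALF = (13, 13, 11)
_TUMOR_CENTER = (32, 32, 46)
_TUMOR_JITTER = 4


@dataclass
class CohortLedger:
    """Ground truth per synthetic patient, plus the tumor/liver masks."""

    table: pd.DataFrame
    tumor_masks: dict = field(default_factory=dict)
    liver_masks: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.table)

    def subset(self, patient_ids) -> "CohortLedger":
        ids = list(patient_ids)
        return CohortLedger(
            table=self.table[self.table.patient_id.isin(ids)].reset_index(drop=True),
            tumor_masks={k: v for k, v in self.tumor_masks.items() if k in ids},
            liver_masks={k: v for k, v in self.liver_masks.items() if k in ids},
        )


def liver_center(spec: CohortSpec) -> tuple[int, int, int]:
    return _LIVER_CENTER


def simulate_cohort(spec: CohortSpec) -> tuple[list[VolumeGrid], CohortLedger]:
    """Generate one volume per synthetic patient plus the truth ledger.

    The ledger records subtype, injection–scan delay, drawn peak SUV and
    radius, necrotic-core flag, the planted tumor sphere's metabolic volume
    and the planted tumor/liver masks (the nominal geometry before any
    segmentation).
    """
    rng = np.random.default_rng(spec.seed)
    subtypes = ["adenocarcinoma"] * spec.n_adeno + ["squamous"] * spec.n_squamous
    volumes: list[VolumeGrid] = []
    rows = []
    tumor_masks: dict[str, VOIMask] = {}
    liver_masks: dict[str, VOIMask] = {}
    spacing = (spec.voxel_mm,) * 3

    for idx, subtype in enumerate(subtypes):
        pid = f"P{idx + 1:03d}"
        if subtype == "adenocarcinoma":
            r_lo, r_hi = spec.adeno_radius_range_mm
            p_lo, p_hi = spec.adeno_peak_suv_range
            has_core = False
        else:
            r_lo, r_hi = spec.squamous_radius_range_mm
            p_lo, p_hi = spec.squamous_peak_suv_range
            has_core = rng.random() < spec.core_prob
        radius_mm = rng.uniform(r_lo, r_hi)
        peak_suv = rng.uniform(p_lo, p_hi)
        delay = rng.uniform(*spec.delay_range_min)
        jitter = rng.integers(-_TUMOR_JITTER, _TUMOR_JITTER + 1, size=3)
        center = tuple(int(c + j) for c, j in zip(_TUMOR_CENTER, jitter))

        if subtype == "adenocarcinoma":
            texture_frac, clip_sd = spec.adeno_texture_frac, spec.adeno_clip_sd
        else:
            texture_frac, clip_sd = spec.squamous_texture_frac, spec.squamous_clip_sd
        texture_length_mm = rng.uniform(*spec.texture_length_range_mm)
        noise_sd_frac = rng.uniform(*spec.noise_sd_frac_range)
        vol, tumor_mask = _render_patient(
            spec, rng, center, radius_mm, peak_suv, has_core,
            texture_frac, texture_length_mm, noise_sd_frac, clip_sd,
        )
        volumes.append(vol)
        tumor_masks[pid] = tumor_mask
        liver_masks[pid] = _liver_block_mask(spec)
        rows.append(
            dict(
                patient_id=pid,
                subtype=subtype,
                delay_min=float(delay),
                peak_suv=float(peak_suv),
                radius_mm=float(radius_mm),
                has_core=bool(has_core),
                tumor_center=center,
                mv_ml=metabolic_volume(tumor_mask, spacing),
            )
        )

    ledger = CohortLedger(pd.DataFrame(rows), tumor_masks, liver_masks)
    return volumes, ledger


def _liver_block_mask(spec: CohortSpec) -> VOIMask:
    mask = np.zeros(spec.grid_shape, dtype=bool)
    c, h = _LIVER_CENTER, _LIVER_HALF
    mask[
        c[0] - h[0] : c[0] + h[0] + 1,
        c[1] - h[1] : c[1] + h[1] + 1,
        c[2] - h[2] : c[2] + h[2] + 1,
    ] = True
    return VOIMask(mask)


def _render_patient(
    spec, rng, tumor_center, radius_mm, peak_suv, has_core,
    texture_frac, texture_length_mm, noise_sd_frac, clip_sd,
):
    shape = spec.grid_shape
    x, y, z = np.ogrid[0 : shape[0], 0 : shape[1], 0 : shape[2]]

    mean = np.full(shape, spec.body_suv, dtype=float)
    mean[_liver_block_mask(spec).mask] = spec.liver_mean_suv

    r_vox = radius_mm / spec.voxel_mm
    dist2 = (
        (x - tumor_center[0]) ** 2
        + (y - tumor_center[1]) ** 2
        + (z - tumor_center[2]) ** 2
    )
    tumor = dist2 <= r_vox**2
    mean[tumor] = peak_suv
    if texture_frac > 0 and texture_length_mm > 0:
        # intra-tumor biological texture: multiplicative correlated field,
        # clipped asymmetrically (shallow cold dips, taller focal hot spots)
        sigma_tex = texture_length_mm * _FWHM_TO_SIGMA / spec.voxel_mm
        tex = ndimage.gaussian_filter(rng.normal(0.0, 1.0, size=shape), sigma_tex)
        sd = tex.std()
        if sd > 0:
            tex /= sd
        lo, hi = clip_sd
        mean[tumor] *= 1.0 + texture_frac * np.clip(tex[tumor], -lo, hi)
    if has_core:
        core = dist2 <= (spec.core_radius_frac * r_vox) ** 2
        mean[core] = spec.core_suv_fraction * peak_suv

    field_ = mean
    if noise_sd_frac > 0:
        field_ = mean + rng.normal(0.0, 1.0, size=shape) * (noise_sd_frac * mean)
    if spec.psf_fwhm_mm > 0:
        sigma = spec.psf_fwhm_mm * _FWHM_TO_SIGMA / spec.voxel_mm
        field_ = ndimage.gaussian_filter(field_, sigma)
    np.clip(field_, 0.0, None, out=field_)
    vol = VolumeGrid(field_, (spec.voxel_mm,) * 3, unit=SUV)
    return vol, VOIMask(tumor)


def apply_exclusions(
    ledger: CohortLedger,
    delay_range_min: tuple[float, float] = (60.0, 90.0),
    mv_min_ml: float = 2.5,
) -> tuple[CohortLedger, dict]:
    """Apply the study's patient-selection filters in order: injection–scan
    delay inside the closed range, then metabolic volume >= the floor.

    Returns the retained ledger plus the exclusion tally per criterion in
    application order.
    """
    t = ledger.table
    lo, hi = delay_range_min
    bad_delay = (t.delay_min < lo) | (t.delay_min > hi)
    bad_mv = ~bad_delay & (t.mv_ml < mv_min_ml)
    tally = {
        "delay_outside_range": int(bad_delay.sum()),
        "mv_below_min": int(bad_mv.sum()),
    }
    keep = t.loc[~bad_delay & ~bad_mv, "patient_id"]
    return ledger.subset(keep), tally
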