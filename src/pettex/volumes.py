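"""3D PET volumes: in-memory lattice, SUV conversion and NIfTI I/O.

A :class:`VolumeGrid` is a plain 3D scalar lattice with voxel spacing and a
unit tag, either raw activity concentration (kBq/mL) or body-weight-normalized
standardized uptake value (SUV).  The conversion between the two uses the
conventional definition

    SUV(x) = C(x) [kBq/mL] * body_weight [kg] / A_scan [MBq]

where ``A_scan`` is the injected activity decay-corrected to scan time.  The
kBq/MBq and g/kg factors cancel under the standard 1 g/mL tissue-density
assumption, so the formula reduces to the ratio above.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import nibabel as nib
import numpy as np

ACTIVITY = "activity"
SUV = "suv"

#: 18F half-life in minutes.
F18_HALF_LIFE_MIN = 109.77


class InvalidMetadataError(ValueError):
    """Acquisition metadata violates its physical constraints."""


class VolumeFormatError(ValueError):
    """An image file does not contain a single-channel 3D volume."""


@dataclass(frozen=True)
class VolumeGrid:
    """A 3D scalar image with isotropic-or-not voxel spacing in mm.

    Parameters
    ----------
    values : ndarray
        3D array of finite, non-negative intensities.
    spacing : tuple of float
        Voxel edge lengths ``(dx, dy, dz)`` in mm, each > 0.
    unit : {"activity", "suv"}
        Intensity unit tag; ``activity`` means kBq/mL.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    unit: str = SUV

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3:
            raise VolumeFormatError(f"expected a 3D lattice, got ndim={values.ndim}")
        if not np.all(np.isfinite(values)):
            raise ValueError("volume contains non-finite values")
        if values.min() < 0:
            raise ValueError("PET intensities must be non-negative")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be three positive lengths, got {spacing}")
        if self.unit not in (ACTIVITY, SUV):
            raise ValueError(f"unknown unit {self.unit!r}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in mL (mm^3 / 1000)."""
        dx, dy, dz = self.spacing
        return dx * dy * dz / 1000.0


@dataclass(frozen=True)
class AcquisitionMeta:
    """Injection and patient metadata needed for the SUV conversion.

    ``decay_interval_min`` is the delay between the activity measurement and
    the scan; 0 means the stated activity already refers to scan time.
    """

    injected_activity_mbq: float
    body_weight_kg: float
    decay_interval_min: float = 0.0
    isotope_half_life_min: float = F18_HALF_LIFE_MIN

    def __post_init__(self) -> None:
        if self.injected_activity_mbq <= 0:
            raise InvalidMetadataError("injected activity must be positive")
        if self.body_weight_kg <= 0:
            raise InvalidMetadataError("body weight must be positive")
        if self.decay_interval_min < 0:
            raise InvalidMetadataError("decay interval must be non-negative")
        if self.isotope_half_life_min <= 0:
            raise InvalidMetadataError("half-life must be positive")

    @property
    def activity_at_scan_mbq(self) -> float:
        """Injected activity decay-corrected to scan time, in MBq."""
        return self.injected_activity_mbq * 2.0 ** (
            -self.decay_interval_min / self.isotope_half_life_min
        )


def to_suv(vol: VolumeGrid, meta: AcquisitionMeta) -> VolumeGrid:
    """Convert an activity-concentration volume (kBq/mL) to SUV.

    The conversion is linear in the voxel values; shape and spacing are
    unchanged and the unit tag becomes ``suv``.
    """
    if vol.unit != ACTIVITY:
        raise ValueError(f"to_suv expects an activity volume, got unit={vol.unit!r}")
    factor = meta.body_weight_kg / meta.activity_at_scan_mbq
    return replace(vol, values=vol.values * factor, unit=SUV)


def read_volume(path, unit: str = SUV) -> VolumeGrid:
    """Read a 3D single-channel NIfTI-1 image.

    Spacing is taken from the header zooms.  A trailing singleton fourth
    dimension is not accepted: the file must be stored as a 3D image.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeFormatError(
            f"{path}: expected a 3D image, got {data.ndim} dimensions"
        )
    zooms = img.header.get_zooms()[:3]
    if len(zooms) < 3 or any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise VolumeFormatError(f"{path}: missing or invalid voxel spacing {zooms}")
    return VolumeGrid(values=np.asarray(data, dtype=float), spacing=tuple(zooms), unit=unit)


def write_volume(vol: VolumeGrid, path) -> None:
    """Write a :class:`VolumeGrid` as NIfTI-1, spacing on the affine diagonal."""
    affine = np.diag(list(vol.spacing) + [1.0])
    img = nib.Nifti1Image(vol.values.astype(np.float32), affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))
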