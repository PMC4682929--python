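"""Volumes of interest: spheres, adaptive-threshold lesion segmentation,
rigid relocation into reference tissue, and metabolic volume.

Three VOI kinds are supported, matching a phantom-plus-patient study design:
voxel-centered spheres drawn in a uniform phantom, lesion masks obtained by a
background-corrected adaptive threshold, and the same lesion geometry
translated (integer voxels, no interpolation) into healthy reference tissue
such as the liver.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volumes import VolumeGrid, SUV


class SegmentationError(RuntimeError):
    """The requested segmentation produced an empty mask."""


class MaskGeometryError(ValueError):
    """A mask operation would leave the volume lattice."""


@dataclass(frozen=True)
class VOIMask:
    """Boolean lattice selecting the voxels of one VOI."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 3:
            raise ValueError("VOI mask must be a 3D boolean lattice")
        object.__setattr__(self, "mask", mask)

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    def indices(self) -> np.ndarray:
        """(n, 3) integer coordinates of the in-mask voxels."""
        return np.argwhere(self.mask)


def sphere_voi(shape_or_vol, center_voxel, diameter_voxels: int) -> VOIMask:
    """Voxel-centered sphere of odd diameter ``d`` (in voxels): include a
    voxel iff its center lies within the integer radius ``(d - 1) / 2``
    (Euclidean, inclusive) of ``center_voxel``.

    The integer radius makes the sphere span exactly ``d`` voxels along each
    axis and makes diameter 3 the intuitive 7-voxel cross (center plus six
    face neighbors); diameter 1 degenerates to the center voxel alone.  Only
    odd diameters are allowed so the sphere is centered on a voxel.
    """
    shape = shape_or_vol.shape if hasattr(shape_or_vol, "shape") else tuple(shape_or_vol)
    d = int(diameter_voxels)
    if d < 1 or d % 2 == 0:
        raise ValueError(f"sphere diameter must be a positive odd integer, got {d}")
    radius = (d - 1) / 2.0
    reach = (d - 1) // 2
    center = tuple(int(c) for c in center_voxel)
    for c, n in zip(center, shape):
        if c - reach < 0 or c + reach >= n:
            raise MaskGeometryError(
                f"sphere of diameter {d} at {center} clipped by volume of shape {shape}"
            )
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    dist2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return VOIMask(dist2 <= radius**2)


def metabolic_volume(mask: VOIMask, spacing) -> float:
    """Metabolic volume in mL: voxel count times voxel volume (mm^3 -> mL)."""
    dx, dy, dz = (float(s) for s in spacing)
    return mask.voxel_count * dx * dy * dz / 1000.0


def relocate_voi(mask: VOIMask, target_center) -> VOIMask:
    """Translate a mask rigidly so its (rounded) centroid lands on
    ``target_center``.  Integer-voxel translation only, so the gray-level
    geometry sampled through the mask is preserved exactly.
    """
    coords = mask.indices()
    if coords.shape[0] == 0:
        raise ValueError("cannot relocate an empty mask")
    centroid = np.round(coords.mean(axis=0)).astype(int)
    shift = np.asarray(target_center, dtype=int) - centroid
    moved = coords + shift
    if moved.min() < 0 or np.any(moved >= np.asarray(mask.shape)):
        raise MaskGeometryError(
            f"translation by {tuple(shift)} clips the mask outside {mask.shape}"
        )
    out = np.zeros(mask.shape, dtype=bool)
    out[moved[:, 0], moved[:, 1], moved[:, 2]] = True
    return VOIMask(out)


_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def adaptive_threshold_segment(
    vol: VolumeGrid,
    seed_voxel,
    *,
    beta: float = 0.3,
    iso_fraction: float = 0.7,
    search_radius_vox: int = 8,
    shell_gap_vox: int = 1,
    shell_width_vox: int = 2,
    mode: str = "adaptive",
    max_fraction: float = 0.4,
) -> VOIMask:
    """Segment a lesion by a background-corrected adaptive threshold.

    The threshold is the contrast-oriented rule

        T = beta * mean(SUV over voxels >= iso_fraction * local SUVmax) + bg

    where the local maximum is searched in a box of ``search_radius_vox``
    around the seed, the high-uptake kernel is the 26-connected component of
    the ``iso_fraction`` isocontour containing that maximum, and ``bg`` is the
    mean SUV in a shell ``shell_gap_vox`` to ``shell_gap_vox+shell_width_vox``
    voxels outside the kernel.  The segmentation is the 26-connected
    component of ``SUV >= T`` anchored at the seed (or at the local maximum
    when the seed itself falls below T, e.g. inside a necrotic core).

    ``mode="fraction"`` replaces the rule by a fixed fraction of the local
    maximum (``T = max_fraction * local SUVmax``).
    """
    if vol.unit != SUV:
        raise ValueError("segmentation operates on SUV volumes")
    values = vol.values
    seed = tuple(int(c) for c in seed_voxel)
    if any(c < 0 or c >= n for c, n in zip(seed, values.shape)):
        raise ValueError(f"seed {seed} outside volume of shape {values.shape}")

    box = tuple(
        slice(max(0, c - search_radius_vox), min(n, c + search_radius_vox + 1))
        for c, n in zip(seed, values.shape)
    )
    local = values[box]
    local_max = float(local.max())
    if local_max <= 0:
        raise SegmentationError("no uptake near the seed (local maximum is zero)")
    max_local_idx = np.unravel_index(int(np.argmax(local)), local.shape)
    max_voxel = tuple(s.start + i for s, i in zip(box, max_local_idx))

    if mode == "fraction":
        threshold = max_fraction * local_max
    elif mode == "adaptive":
        kernel_all = values >= iso_fraction * local_max
        labels, _ = ndimage.label(kernel_all, structure=_STRUCT26)
        kernel = labels == labels[max_voxel]
        inner = ndimage.binary_dilation(kernel, _STRUCT26, iterations=shell_gap_vox)
        outer = ndimage.binary_dilation(
            kernel, _STRUCT26, iterations=shell_gap_vox + shell_width_vox
        )
        shell = outer & ~inner
        background = float(values[shell].mean()) if shell.any() else 0.0
        threshold = beta * float(values[kernel].mean()) + background
    else:
        raise ValueError(f"unknown segmentation mode {mode!r}")

    above = values >= threshold
    labels, _ = ndimage.label(above, structure=_STRUCT26)
    anchor = seed if above[seed] else max_voxel
    if not above[anchor]:
        raise SegmentationError(
            f"threshold {threshold:.3g} SUV excludes both seed and local maximum"
        )
    mask = labels == labels[anchor]
    if not mask.any():
        raise SegmentationError("adaptive threshold produced an empty segmentation")
    if _touches_border(mask):
        warnings.warn(
            "segmentation touches the volume border; VOI may be truncated",
            stacklevel=2,
        )
    return VOIMask(mask)


def _touches_border(mask: np.ndarray) -> bool:
    return bool(
        mask[0].any() or mask[-1].any()
        or mask[:, 0].any() or mask[:, -1].any()
        or mask[:, :, 0].any() or mask[:, :, -1].any()
    )
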