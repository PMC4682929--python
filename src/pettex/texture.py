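"""Texture matrices and indices for a resampled VOI.

Three matrices are built from the discrete gray levels inside a VOI:

* the **co-occurrence matrix** (CM), accumulated symmetrically for voxel
  pairs at distance 1 along each of the 13 sign-free 3D directions;
* the **gray-level run-length matrix** (GRLM), counting maximal collinear
  runs of identical level per direction;
* the **gray-level zone matrix** (GZLM), counting 26-connected
  equal-level zones over the full 3D mask.

CM and GRLM indices are the unweighted mean over directions that contain at
least one valid pair/run; a direction with no valid voxel pair in a thin VOI
is undefined rather than homogeneous, so it is dropped from the average.
Seven indices follow: homogeneity and entropy (CM), SRE, LRE and RLNU
(GRLM), LGZE and HGZE (GZLM) — plus CM contrast, SUVmax and metabolic
volume, collected in a :class:`TIVector`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .resampling import ResamplingSpec, ResampledVOI, resample
from .voi import VOIMask, metabolic_volume
from .volumes import VolumeGrid, SUV


class DegenerateTextureError(RuntimeError):
    """No direction holds a valid voxel pair (e.g. a single-voxel VOI)."""


def direction_set() -> tuple[tuple[int, int, int], ...]:
    """The 13 unique displacement vectors with components in {-1,0,1},
    excluding the origin and taken modulo sign (first non-zero component
    positive)."""
    dirs = []
    for d in itertools.product((-1, 0, 1), repeat=3):
        if d == (0, 0, 0):
            continue
        first = next(c for c in d if c != 0)
        if first > 0:
            dirs.append(d)
    return tuple(dirs)


DIRECTIONS = direction_set()

#: The seven texture indices of the study, in table order.
SEVEN_TI = ("homogeneity", "entropy", "sre", "lre", "rlnu", "lgze", "hgze")
ALL_TI = ("homogeneity", "entropy", "contrast", "sre", "lre", "rlnu", "lgze", "hgze")

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)
_STRUCT6 = ndimage.generate_binary_structure(3, 1)


def _offset_slices(shape, d):
    src, dst = [], []
    for n, o in zip(shape, d):
        if o >= 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    return tuple(src), tuple(dst)


def levels_volume(rv: ResampledVOI, mask: VOIMask) -> np.ndarray:
    """Scatter the flat level array back onto the lattice (0 outside mask)."""
    if rv.levels.size != mask.voxel_count:
        raise ValueError("resampled VOI does not match the mask voxel count")
    out = np.zeros(mask.shape, dtype=np.int64)
    out[mask.mask] = rv.levels
    return out


@dataclass(frozen=True)
class TextureMatrices:
    """Per-direction CM (normalized) and GRLM (counts), plus the 3D GZLM.

    ``cm[d]`` is ``None`` for directions with no valid pair.  ``grlm[d]``
    rows are gray levels, columns run lengths; ``gzlm`` rows are gray levels,
    columns zone sizes.  ``h_grlm``/``h_gzlm`` are the total run/zone counts.
    """

    cm: tuple
    grlm: tuple
    gzlm: np.ndarray
    h_grlm: tuple
    h_gzlm: int
    voxel_count: int


def build_cm(levels: np.ndarray, mask: np.ndarray, directions=DIRECTIONS):
    """Symmetric co-occurrence matrices, one per direction, normalized to
    probabilities; ``None`` where the direction has no valid in-mask pair."""
    lmax = int(levels[mask].max())
    out = []
    for d in directions:
        src, dst = _offset_slices(levels.shape, d)
        valid = mask[src] & mask[dst]
        i = levels[src][valid]
        if i.size == 0:
            out.append(None)
            continue
        j = levels[dst][valid]
        m = np.zeros((lmax, lmax), dtype=float)
        np.add.at(m, (i - 1, j - 1), 1.0)
        np.add.at(m, (j - 1, i - 1), 1.0)
        out.append(m / m.sum())
    return tuple(out)


def cm_indices(cms, log_base: float = 2.0):
    """Direction-averaged (homogeneity, entropy, contrast) from normalized
    co-occurrence matrices."""
    homo, ent, contr = [], [], []
    for m in cms:
        if m is None:
            continue
        lmax = m.shape[0]
        i, j = np.meshgrid(np.arange(1, lmax + 1), np.arange(1, lmax + 1), indexing="ij")
        p = m[m > 0]
        homo.append(float((m / (1.0 + np.abs(i - j))).sum()))
        ent.append(float(-(p * np.log(p)).sum() / np.log(log_base)))
        contr.append(float((m * (i - j) ** 2).sum()))
    if not homo:
        raise DegenerateTextureError("all co-occurrence directions are empty")
    return float(np.mean(homo)), float(np.mean(ent)), float(np.mean(contr))


def build_grlm(levels: np.ndarray, mask: np.ndarray, directions=DIRECTIONS):
    """Run-length matrices, one per direction.

    A run is a maximal collinear sequence of in-mask voxels sharing one gray
    level; it ends at a mask boundary or level change.  Every in-mask voxel
    belongs to exactly one run per direction, so each matrix's run-length
    weighted mass equals the voxel count.
    """
    shape = np.asarray(levels.shape)
    lmax = int(levels[mask].max())
    out = []
    for d in directions:
        dv = np.asarray(d)
        # run starts: predecessor along -d is out of mask or differs in level
        prev_same = np.zeros(levels.shape, dtype=bool)
        src, dst = _offset_slices(levels.shape, tuple(-c for c in d))
        prev_same[src] = mask[src] & mask[dst] & (levels[src] == levels[dst])
        starts = mask & ~prev_same
        coords = np.argwhere(starts)
        run_levels = levels[starts]
        # order of levels[boolean] is C-order, same as argwhere: keep aligned
        lengths = np.ones(coords.shape[0], dtype=np.int64)
        active = np.arange(coords.shape[0])
        while active.size:
            nxt = coords[active] + dv * lengths[active, None]
            inb = np.all((nxt >= 0) & (nxt < shape), axis=1)
            cand = active[inb]
            pos = nxt[inb]
            same = mask[pos[:, 0], pos[:, 1], pos[:, 2]] & (
                levels[pos[:, 0], pos[:, 1], pos[:, 2]] == run_levels[cand]
            )
            active = cand[same]
            lengths[active] += 1
        g = np.zeros((lmax, int(lengths.max())), dtype=float)
        np.add.at(g, (run_levels - 1, lengths - 1), 1.0)
        out.append(g)
    return tuple(out)


def grlm_indices(grlms):
    """Direction-averaged (SRE, LRE, RLNU)."""
    sre, lre, rlnu = [], [], []
    for g in grlms:
        h = g.sum()
        if h == 0:
            continue
        j = np.arange(1, g.shape[1] + 1, dtype=float)
        sre.append(float((g / j**2).sum() / h))
        lre.append(float((g * j**2).sum() / h))
        rlnu.append(float((g.sum(axis=0) ** 2).sum() / h))
    if not sre:
        raise DegenerateTextureError("no runs in any direction")
    return float(np.mean(sre)), float(np.mean(lre)), float(np.mean(rlnu))


def build_gzlm(levels: np.ndarray, mask: np.ndarray, connectivity: int = 26):
    """Zone matrix: zones are maximal connected components of equal gray
    level within the mask (26-connectivity by default, 6 optional)."""
    structure = _STRUCT26 if connectivity == 26 else _STRUCT6
    lmax = int(levels[mask].max())
    records = []  # (level, size)
    max_size = 1
    for g in np.unique(levels[mask]):
        labels, n = ndimage.label(mask & (levels == g), structure=structure)
        if n == 0:
            continue
        sizes = np.bincount(labels[labels > 0])[1:]
        for s in sizes:
            records.append((int(g), int(s)))
            max_size = max(max_size, int(s))
    z = np.zeros((lmax, max_size), dtype=float)
    for g, s in records:
        z[g - 1, s - 1] += 1.0
    return z


def gzlm_indices(gzlm):
    """(LGZE, HGZE) from the zone matrix."""
    h = gzlm.sum()
    if h == 0:
        raise DegenerateTextureError("zone matrix is empty")
    i = np.arange(1, gzlm.shape[0] + 1, dtype=float)[:, None]
    lgze = float((gzlm / i**2).sum() / h)
    hgze = float((gzlm * i**2).sum() / h)
    return lgze, hgze


def build_matrices(
    rv: ResampledVOI, mask: VOIMask, *, connectivity: int = 26
) -> TextureMatrices:
    """All three texture matrices for one resampled VOI."""
    levels = levels_volume(rv, mask)
    m = mask.mask
    cms = build_cm(levels, m)
    grlms = build_grlm(levels, m)
    gzlm = build_gzlm(levels, m, connectivity=connectivity)
    return TextureMatrices(
        cm=cms,
        grlm=grlms,
        gzlm=gzlm,
        h_grlm=tuple(int(g.sum()) for g in grlms),
        h_gzlm=int(gzlm.sum()),
        voxel_count=mask.voxel_count,
    )


@dataclass(frozen=True)
class TIVector:
    """The texture indices of one VOI under one resampling spec, together
    with SUVmax (pre-resampling), metabolic volume and provenance."""

    homogeneity: float
    entropy: float
    contrast: float
    sre: float
    lre: float
    rlnu: float
    lgze: float
    hgze: float
    suvmax: float
    mv: float
    n_voxels: int
    n_clipped: int
    spec: ResamplingSpec
    provenance: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {name: getattr(self, name) for name in ALL_TI}
        d.update(
            method=self.spec.label,
            D=self.spec.levels,
            low=self.spec.low if self.spec.method == "ar" else float("nan"),
            high=self.spec.high if self.spec.method == "ar" else float("nan"),
            suvmax_suv=self.suvmax,
            mv_ml=self.mv,
            n_voxels=self.n_voxels,
            n_clipped=self.n_clipped,
        )
        return d


def extract_ti(
    vol: VolumeGrid,
    mask: VOIMask,
    spec: ResamplingSpec,
    *,
    log_base: float = 2.0,
    connectivity: int = 26,
    provenance: dict | None = None,
) -> TIVector:
    """Resample the in-mask SUVs, build the texture matrices and compute the
    full index vector for one VOI."""
    if vol.unit != SUV:
        raise ValueError("texture extraction expects an SUV volume")
    if mask.shape != vol.shape:
        raise ValueError("mask and volume shapes differ")
    if mask.voxel_count == 0:
        raise ValueError("empty VOI")
    suv_in_mask = vol.values[mask.mask]
    rv = resample(suv_in_mask, spec)
    mats = build_matrices(rv, mask, connectivity=connectivity)
    homogeneity, entropy, contrast = cm_indices(mats.cm, log_base=log_base)
    sre, lre, rlnu = grlm_indices(mats.grlm)
    lgze, hgze = gzlm_indices(mats.gzlm)
    return TIVector(
        homogeneity=homogeneity,
        entropy=entropy,
        contrast=contrast,
        sre=sre,
        lre=lre,
        rlnu=rlnu,
        lgze=lgze,
        hgze=hgze,
        suvmax=float(suv_in_mask.max()),
        mv=metabolic_volume(mask, vol.spacing),
        n_voxels=mask.voxel_count,
        n_clipped=rv.n_clipped,
        spec=spec,
        provenance=dict(provenance or {}),
    )
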