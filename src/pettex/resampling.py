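"""Gray-level resampling of SUV values inside a VOI.

Two discretization schemes are implemented:

* **Relative resampling (RR)** — the conventional min–max scheme,
  ``level(x) = round(D * (I(x) - SUVmin) / (SUVmax - SUVmin)) + 1``,
  stretching each VOI to its own intensity range.  RR levels are invariant
  under any increasing affine map of the intensities, which is exactly why
  RR-based texture indices discard the absolute SUV scale.
* **Absolute resampling (AR)** — fixed SUV bounds shared by all VOIs,
  ``level(x) = round(D * (I(x) - low) / (high - low)) + 1`` with intensities
  clipped to ``[low, high]``.  Defaults are 0–20 SUV with D = 64 levels,
  i.e. a bin width of 0.3125 SUV; presets AR15/AR20/AR25 vary the high bound.

Rounding is half-up (0.5 rounds to 1), fixed explicitly so the texture
matrices do not silently change under the platform's bankers' rounding.
The raw rounded value lies in 0..D; a +1 shift is applied identically to
both schemes so levels occupy 1..D+1 and gray-level-weighted indices with
1/i^2 terms stay defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

RR = "rr"
AR = "ar"


@dataclass(frozen=True)
class ResamplingSpec:
    """How SUVs are mapped to discrete gray levels.

    ``low``/``high`` are only meaningful for the AR method; ``levels`` is the
    number D of discretization steps (gray levels run 1..D+1).
    """

    method: str
    levels: int = 64
    low: float = 0.0
    high: float = 20.0

    def __post_init__(self) -> None:
        if self.method not in (RR, AR):
            raise ValueError(f"unknown resampling method {self.method!r}")
        if self.levels < 2:
            raise ValueError("number of gray levels D must be >= 2")
        if self.method == AR and self.high <= self.low:
            raise ValueError("AR high bound must exceed the low bound")

    @property
    def bin_width(self) -> float:
        """SUV width of one AR bin: (high - low) / D."""
        if self.method != AR:
            raise ValueError("bin width is defined for absolute resampling only")
        return (self.high - self.low) / self.levels

    @property
    def label(self) -> str:
        if self.method == RR:
            return "rr"
        return f"ar{self.high:g}"


RR_SPEC = ResamplingSpec(RR)
AR15 = ResamplingSpec(AR, high=15.0)
AR20 = ResamplingSpec(AR, high=20.0)
AR25 = ResamplingSpec(AR, high=25.0)

_PRESETS = {"rr": RR_SPEC, "ar15": AR15, "ar20": AR20, "ar25": AR25, "ar": AR20}


def preset(name: str) -> ResamplingSpec:
    """Look up a named scheme: ``rr``, ``ar15``, ``ar20`` or ``ar25``."""
    try:
        return _PRESETS[name.lower()]
    except KeyError:
        raise ValueError(f"unknown resampling preset {name!r}") from None


def fixed_bin_width(width: float, levels: int = 64) -> ResamplingSpec:
    """Fixed-bin-width scheme expressed as AR: width w with D levels is AR
    with bounds [0, w*D] (e.g. 0.5 SUV bins with 64 levels = AR high 32)."""
    if width <= 0:
        raise ValueError("bin width must be positive")
    return ResamplingSpec(AR, levels=levels, low=0.0, high=width * levels)


@dataclass(frozen=True)
class ResampledVOI:
    """Discrete gray levels for the in-mask voxels, with provenance.

    ``levels`` is a flat integer array aligned with the mask's voxel order
    (C-order scan of the lattice); each entry lies in 1..D+1.
    """

    levels: np.ndarray
    spec: ResamplingSpec
    source_suvmin: float
    source_suvmax: float
    n_clipped: int = 0

    def __post_init__(self) -> None:
        levels = np.asarray(self.levels, dtype=np.int64)
        if levels.size == 0:
            raise ValueError("resampled VOI is empty")
        if levels.min() < 1 or levels.max() > self.spec.levels + 1:
            raise ValueError("gray levels outside 1..D+1")
        object.__setattr__(self, "levels", levels)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def resample_rr(suv_values, D: int = 64) -> ResampledVOI:
    """Relative (min–max) resampling.  A constant region maps to level 1."""
    values = np.asarray(suv_values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("cannot resample an empty VOI")
    vmin, vmax = float(values.min()), float(values.max())
    if vmax == vmin:
        levels = np.ones(values.shape, dtype=np.int64)
    else:
        levels = _round_half_up(D * (values - vmin) / (vmax - vmin)).astype(np.int64) + 1
    return ResampledVOI(levels, ResamplingSpec(RR, levels=D), vmin, vmax)


def resample_ar(
    suv_values, D: int = 64, low: float = 0.0, high: float = 20.0
) -> ResampledVOI:
    """Absolute (fixed-bound) resampling; out-of-range values are clipped and
    counted in ``n_clipped``."""
    values = np.asarray(suv_values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("cannot resample an empty VOI")
    spec = ResamplingSpec(AR, levels=D, low=low, high=high)
    n_clipped = int(np.count_nonzero((values < low) | (values > high)))
    clipped = np.clip(values, low, high)
    levels = _round_half_up(D * (clipped - low) / (high - low)).astype(np.int64) + 1
    return ResampledVOI(levels, spec, float(values.min()), float(values.max()), n_clipped)


def resample(suv_values, spec: ResamplingSpec) -> ResampledVOI:
    """Dispatch on the spec's method."""
    if spec.method == RR:
        return resample_rr(suv_values, D=spec.levels)
    return resample_ar(suv_values, D=spec.levels, low=spec.low, high=spec.high)
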