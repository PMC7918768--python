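"""Volume preprocessing for PDFF texture analysis.

A PDFF (proton density fat fraction) map stores, per voxel, the fraction of
MR-visible protons attributable to fat, in percent.  Texture analysis needs
three preprocessing steps before features are computed over a muscle ROI:

1. isotropic resampling, so that the 26-neighborhood used by the
   co-occurrence analysis steps the same physical distance along every axis;
2. extraction of the in-mask voxel values (for mean PDFF and the histogram
   features);
3. uniform gray-level quantization of the in-mask values (for the
   co-occurrence features).

Axis convention: array axis 0 = x (left/right), axis 1 = y
(anterior/posterior), axis 2 = z (slice direction).  Voxel indexing is
0-based; a voxel's physical center sits at ``(index + 0.5) * spacing`` so
resampling is center-aligned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


class DegenerateQuantizationWarning(UserWarning):
    """Raised when an ROI is constant so no gray-level range exists."""


@dataclass
class PDFFVolume:
    """A 3D fat-fraction map in percent with per-axis voxel spacing in mm."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("PDFF map must be 3D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("PDFF map contains non-finite values")
        if self.values.min() < 0 or self.values.max() > 100:
            raise ValueError("PDFF values must lie in [0, 100] percent")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be three positive numbers")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass
class ROIMask:
    """Binary mask over a PDFF volume, labeled by muscle group and side.

    ``muscle_group`` is ``"EXT"`` (quadriceps / knee extensors) or ``"FLEX"``
    (ischiocrural / knee flexors); ``side`` is ``"left"`` or ``"right"``.
    """

    values: np.ndarray
    muscle_group: str = "EXT"
    side: str = "left"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise ValueError("mask must be 3D")
        if self.muscle_group not in ("EXT", "FLEX"):
            raise ValueError("muscle_group must be 'EXT' or 'FLEX'")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        if int(self.values.sum()) < 27:
            raise ValueError("ROI must contain at least 27 voxels")

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())


@dataclass
class QuantizedROI:
    """ROI gray levels quantized to integers 1..Ng (0 outside the mask)."""

    levels: np.ndarray
    Ng: int
    level_edges: np.ndarray
    degenerate: bool = False
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.int32)
        if self.mask is None:
            self.mask = self.levels > 0
        self.mask = np.asarray(self.mask).astype(bool)
        inmask = self.levels[self.mask]
        if inmask.size and (inmask.min() < 1 or inmask.max() > self.Ng):
            raise ValueError("in-mask levels must lie in [1, Ng]")
        edges = np.asarray(self.level_edges, dtype=np.float64)
        if edges.size and not self.degenerate and np.any(np.diff(edges) <= 0):
            raise ValueError("level edges must be strictly increasing")


def resample_isotropic(
    vol: PDFFVolume, mask: ROIMask, target_mm: float = 2.0
) -> tuple[PDFFVolume, ROIMask]:
    """Resample map and mask to isotropic spacing ``target_mm``.

    The map is interpolated trilinearly, the mask by nearest neighbor and
    re-binarized at 0.5.  Output voxel centers are aligned to input voxel
    centers (center-aligned convention), and physical extents are preserved
    to within one voxel.
    """
    if target_mm <= 0:
        raise ValueError("target spacing must be positive")
    if vol.shape != mask.values.shape:
        raise ValueError("volume and mask shapes differ")
    spacing = vol.spacing_mm
    new_shape = tuple(
        max(1, int(round(n * s / target_mm))) for n, s in zip(vol.shape, spacing)
    )
    coords = np.meshgrid(
        *[
            (np.arange(m) + 0.5) * target_mm / s - 0.5
            for m, s in zip(new_shape, spacing)
        ],
        indexing="ij",
    )
    new_vals = ndimage.map_coordinates(vol.values, coords, order=1, mode="nearest")
    new_mask = (
        ndimage.map_coordinates(
            mask.values.astype(np.float64), coords, order=0, mode="nearest"
        )
        > 0.5
    )
    out_vol = PDFFVolume(np.clip(new_vals, 0.0, 100.0), (target_mm,) * 3)
    out_mask = ROIMask(new_mask, mask.muscle_group, mask.side)
    return out_vol, out_mask


def extract_roi_values(vol: PDFFVolume, mask: ROIMask) -> np.ndarray:
    """Return in-mask voxel values in lexicographic voxel-index order."""
    if vol.shape != mask.values.shape:
        raise ValueError("volume and mask shapes differ")
    vals = vol.values[mask.values]
    if vals.size == 0:
        raise ValueError("empty mask")
    return vals


def mean_pdff(values: np.ndarray) -> float:
    """Arithmetic mean fat fraction of an ROI value vector, in percent."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("empty value vector")
    return float(values.mean())


def quantize(
    vol: PDFFVolume,
    mask: ROIMask,
    Ng: int = 200,
    window: str = "roi",
) -> QuantizedROI:
    """Uniformly quantize in-mask gray levels to integers 1..Ng.

    ``window='roi'`` (default) places the Ng equal-width bins over the
    in-mask [min, max]; ``window='fixed'`` uses the physical [0, 100] percent
    range instead.  The mapping is ``level(v) = ceil(Ng * (v - lo) / (hi -
    lo))`` with ``level(lo) = 1``, so the maximum maps to Ng.  A constant ROI
    has no range: every voxel gets level 1 and the result is flagged
    degenerate (downstream features handle this case explicitly).
    """
    if Ng < 2:
        raise ValueError("Ng must be at least 2")
    if window not in ("roi", "fixed"):
        raise ValueError("window must be 'roi' or 'fixed'")
    vals = extract_roi_values(vol, mask)
    if window == "roi":
        lo, hi = float(vals.min()), float(vals.max())
    else:
        lo, hi = 0.0, 100.0
    levels = np.zeros(vol.shape, dtype=np.int32)
    if hi <= lo:
        warnings.warn(
            "constant ROI: quantization is degenerate, all voxels -> level 1",
            DegenerateQuantizationWarning,
            stacklevel=2,
        )
        levels[mask.values] = 1
        return QuantizedROI(
            levels, Ng, np.array([lo, lo]), degenerate=True, mask=mask.values.copy()
        )
    lv = np.ceil(Ng * (vals - lo) / (hi - lo))
    lv[vals == lo] = 1
    levels[mask.values] = np.clip(lv, 1, Ng).astype(np.int32)
    edges = np.linspace(lo, hi, Ng + 1)
    return QuantizedROI(levels, Ng, edges, degenerate=False, mask=mask.values.copy())
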