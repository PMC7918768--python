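"""3D gray-level co-occurrence matrices and Haralick-type texture features.

A GLCM for displacement ``d`` holds the joint probability that two in-mask
voxels separated by ``d`` have quantized levels (i, j).  With unit offsets,
the 26 direct neighbors of a voxel collapse to 13 canonical directions (one
per +/- pair); computing the eight second-order features per direction and
averaging the 13 results makes the feature set invariant to axis-aligned
rotations of the volume.

Accumulation is symmetric (d and -d both counted), so the matrix is
symmetric and its two marginals coincide (mu_x = mu_y, sigma_x = sigma_y),
which simplifies the correlation feature.

Feature definitions over the normalized matrix p(i, j), levels 1..Ng:

* energy        = sum p^2
* entropy       = -sum p log2 p              (0 log 0 := 0; log base configurable)
* contrast      = sum (i - j)^2 p
* homogeneity   = sum p / (1 + |i - j|)
* correlation   = sum (i - mu_x)(j - mu_y) p / (sigma_x sigma_y)
* variance      = sum (i - mu)^2 p           (mu = mean level over the GLCM)
* sum_average   = sum_{k=2}^{2 Ng} k p_{x+y}(k)
* dissimilarity = sum |i - j| p

A constant ROI gives sigma_x = 0; correlation is then reported as NaN
("missing"), not an error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .preprocess import QuantizedROI

#: The 13 canonical unit displacements (one per +/- pair of the 26 neighbors).
DIRECTIONS: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0),
    (0, 1, 0),
    (0, 0, 1),
    (1, 1, 0),
    (1, -1, 0),
    (1, 0, 1),
    (1, 0, -1),
    (0, 1, 1),
    (0, 1, -1),
    (1, 1, 1),
    (1, 1, -1),
    (1, -1, 1),
    (-1, 1, 1),
)

FEATURE_NAMES: tuple[str, ...] = (
    "energy",
    "entropy",
    "contrast",
    "homogeneity",
    "correlation",
    "variance",
    "sum_average",
    "dissimilarity",
)


class EmptyGLCMError(ValueError):
    """No co-occurring in-mask voxel pair exists for a direction."""


@dataclass(frozen=True)
class Direction:
    offset: tuple[int, int, int]

    def __post_init__(self) -> None:
        o = tuple(int(c) for c in self.offset)
        if o not in DIRECTIONS and tuple(-c for c in o) not in DIRECTIONS:
            raise ValueError(f"{o} is not one of the 13 canonical directions")
        object.__setattr__(self, "offset", o)

    @property
    def length(self) -> float:
        return math.sqrt(sum(c * c for c in self.offset))


@dataclass
class GLCM:
    """Normalized symmetric co-occurrence matrix for one direction."""

    p: np.ndarray
    Ng: int
    direction: Direction
    pair_count: int

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=np.float64)
        if self.p.shape != (self.Ng, self.Ng):
            raise ValueError("GLCM must be Ng x Ng")


@dataclass(frozen=True)
class SecondOrderFeatures:
    energy: float
    entropy: float
    contrast: float
    homogeneity: float
    correlation: float
    variance: float
    sum_average: float
    dissimilarity: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


def _pair_counts(q: QuantizedROI, offset: tuple[int, int, int]) -> np.ndarray:
    """Integer counts of ordered in-mask level pairs at displacement ``offset``."""
    lv = q.levels
    shape = lv.shape
    src = []
    dst = []
    for ax, d in enumerate(offset):
        n = shape[ax]
        if abs(d) >= n:
            return np.zeros((q.Ng, q.Ng), dtype=np.int64)
        if d >= 0:
            src.append(slice(0, n - d))
            dst.append(slice(d, n))
        else:
            src.append(slice(-d, n))
            dst.append(slice(0, n + d))
    a = lv[tuple(src)]
    b = lv[tuple(dst)]
    valid = (a > 0) & (b > 0)
    ai = a[valid].astype(np.int64) - 1
    bi = b[valid].astype(np.int64) - 1
    flat = np.bincount(ai * q.Ng + bi, minlength=q.Ng * q.Ng)
    return flat.reshape(q.Ng, q.Ng)


def compute_glcm(q: QuantizedROI, d: Direction | tuple[int, int, int]) -> GLCM:
    """Symmetric, normalized GLCM of a quantized ROI for one direction.

    Ordered pairs (v, v+d) with both endpoints in-mask are counted, the
    reverse pairs (accumulating -d) added, and the matrix normalized by the
    total pair count.  Raises :class:`EmptyGLCMError` if no pair exists.
    """
    if not isinstance(d, Direction):
        d = Direction(d)
    counts = _pair_counts(q, d.offset)
    counts = counts + counts.T
    total = int(counts.sum())
    if total == 0:
        raise EmptyGLCMError(f"no in-mask voxel pairs for direction {d.offset}")
    return GLCM(counts / total, q.Ng, d, total)


@lru_cache(maxsize=8)
def _weight_matrices(Ng: int) -> dict[str, np.ndarray]:
    i = np.arange(1, Ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    return {
        "i": ii,
        "j": jj,
        "diff2": (ii - jj) ** 2,
        "absdiff": np.abs(ii - jj),
        "inv1p": 1.0 / (1.0 + np.abs(ii - jj)),
        "sum": ii + jj,
    }


def glcm_features(g: GLCM, log_base: float = 2.0) -> SecondOrderFeatures:
    """The eight second-order features of one normalized GLCM."""
    p = g.p
    total = p.sum()
    if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
        raise ValueError("GLCM is not normalized")
    w = _weight_matrices(g.Ng)
    energy = float(np.sum(p * p))
    nz = p[p > 0]
    entropy = float(-np.sum(nz * (np.log(nz) / math.log(log_base))))
    contrast = float(np.sum(w["diff2"] * p))
    homogeneity = float(np.sum(w["inv1p"] * p))
    dissimilarity = float(np.sum(w["absdiff"] * p))
    px = p.sum(axis=1)
    levels = np.arange(1, g.Ng + 1, dtype=np.float64)
    mu_x = float(np.sum(levels * px))
    var_x = float(np.sum((levels - mu_x) ** 2 * px))
    # symmetric matrix: mu_y = mu_x, sigma_y = sigma_x
    if var_x > 0:
        correlation = float(
            np.sum((w["i"] - mu_x) * (w["j"] - mu_x) * p) / var_x
        )
    else:
        correlation = float("nan")
    variance = var_x  # sum (i - mu)^2 p over the matrix = marginal variance
    sum_average = float(np.sum(w["sum"] * p))
    return SecondOrderFeatures(
        energy=energy,
        entropy=entropy,
        contrast=contrast,
        homogeneity=homogeneity,
        correlation=correlation,
        variance=variance,
        sum_average=sum_average,
        dissimilarity=dissimilarity,
    )


def _direction_weights(weighting: str) -> np.ndarray:
    if weighting == "uniform":
        return np.ones(len(DIRECTIONS))
    if weighting == "inverse_length":
        return np.array([1.0 / Direction(o).length for o in DIRECTIONS])
    raise ValueError("weighting must be 'uniform' or 'inverse_length'")


def rotation_invariant_features(
    q: QuantizedROI,
    log_base: float = 2.0,
    weighting: str = "uniform",
    mode: str = "averaged",
) -> SecondOrderFeatures:
    """Direction-averaged second-order features of a quantized ROI.

    ``mode='averaged'`` (default) computes the eight features per direction
    and takes the (weighted) mean over the 13 directions — the averaging
    makes the result invariant under axis-aligned rotations.  Directions
    with no valid pair are excluded from the mean.  A missing correlation
    propagates as missing only if missing in every direction.

    ``mode='pooled'`` instead merges the pair counts of all directions into
    one matrix and computes the features once (provided for comparison).
    """
    if mode not in ("averaged", "pooled"):
        raise ValueError("mode must be 'averaged' or 'pooled'")
    weights = _direction_weights(weighting)
    if mode == "pooled":
        counts = np.zeros((q.Ng, q.Ng), dtype=np.float64)
        for wgt, off in zip(weights, DIRECTIONS):
            c = _pair_counts(q, off)
            counts += wgt * (c + c.T)
        total = counts.sum()
        if total == 0:
            raise EmptyGLCMError("no in-mask voxel pairs in any direction")
        g = GLCM(counts / total, q.Ng, Direction((1, 0, 0)), int(round(total)))
        return glcm_features(g, log_base=log_base)

    per_dir: list[SecondOrderFeatures] = []
    used_w: list[float] = []
    for wgt, off in zip(weights, DIRECTIONS):
        try:
            g = compute_glcm(q, off)
        except EmptyGLCMError:
            continue
        per_dir.append(glcm_features(g, log_base=log_base))
        used_w.append(wgt)
    if not per_dir:
        raise EmptyGLCMError("no in-mask voxel pairs in any direction")
    wa = np.asarray(used_w)
    out: dict[str, float] = {}
    for name in FEATURE_NAMES:
        vals = np.array([getattr(f, name) for f in per_dir])
        if name == "correlation":
            ok = ~np.isnan(vals)
            out[name] = (
                float(np.sum(wa[ok] * vals[ok]) / np.sum(wa[ok]))
                if ok.any()
                else float("nan")
            )
        else:
            out[name] = float(np.sum(wa * vals) / np.sum(wa))
    return SecondOrderFeatures(**out)
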