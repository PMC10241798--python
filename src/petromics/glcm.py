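"""Gray-level co-occurrence matrix (GLCM) texture features.

The in-mask SUV range is discretized into G equal-width gray levels
(1..G inside the mask, 0 outside).  Voxel pairs at unit displacement are
counted into a G x G matrix, accumulated over a direction set, optionally
symmetrized (each pair also counted reversed), and normalized to
probabilities P(i, j).  Four classical texture scalars are computed:

    contrast     C   = sum_ij |i - j|^2 P(i, j)
    correlation  COR = sum_ij (i - mu_i)(j - mu_j) P(i, j) / (sigma_i sigma_j)
    energy       En  = sum_ij P(i, j)^2
    homogeneity  H   = sum_ij P(i, j) / (1 + |i - j|)

with mu/sigma the marginal moments of P.  Two direction modes are provided:
``"3d"`` merges the 13 unique 3D unit-neighbor directions into a single
matrix (the modern volumetric convention, rotation-fairer) and
``"2d-axial"`` uses the 4 in-plane directions accumulated over slices
(mirroring classic per-slice 2D tools).  Offsets are merged into one matrix
before feature computation rather than averaging per-direction features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, DegenerateInputError
from .io import SUVVolume
from .segmentation import VOIMask

__all__ = [
    "LevelVolume",
    "GLCMMatrix",
    "TextureFeatures",
    "OFFSETS_3D",
    "OFFSETS_2D_AXIAL",
    "discretize",
    "build_glcm",
    "glcm_features",
    "texture_pipeline",
]

#: The 13 unique unit-neighbor displacement directions in 3D (one per
#: antipodal pair of the 26-neighborhood).
OFFSETS_3D: tuple[tuple[int, int, int], ...] = tuple(
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
)

#: The 4 unique in-plane directions (axial slices = last axis fixed).
OFFSETS_2D_AXIAL: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0),
    (0, 1, 0),
    (1, 1, 0),
    (1, -1, 0),
)


@dataclass
class LevelVolume:
    """Integer gray-level field: 1..G inside the mask, 0 outside."""

    levels: np.ndarray
    n_levels: int
    discretization_range: tuple[float, float]
    constant: bool = False  # flagged when the in-mask signal had zero spread

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels)
        inside = self.levels[self.levels > 0]
        if inside.size and (inside.min() < 1 or inside.max() > self.n_levels):
            raise DataError("in-mask levels must lie in [1, n_levels]")


@dataclass
class GLCMMatrix:
    """Normalized co-occurrence probability matrix."""

    P: np.ndarray
    offsets: tuple[tuple[int, int, int], ...]
    symmetric: bool = True

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=np.float64)
        if self.P.ndim != 2 or self.P.shape[0] != self.P.shape[1]:
            raise DataError("GLCM must be a square matrix")
        if (self.P < 0).any():
            raise DataError("GLCM entries must be non-negative")
        total = self.P.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise DataError(f"GLCM must be normalized to sum 1, sums to {total}")


@dataclass(frozen=True)
class TextureFeatures:
    contrast: float
    correlation: float  # NaN when undefined (constant image)
    energy: float
    homogeneity: float
    correlation_note: str = ""


def discretize(
    vol: SUVVolume,
    mask: VOIMask,
    n_levels: int = 8,
    value_range: tuple[float, float] | None = None,
) -> LevelVolume:
    """Equal-width binning of in-mask SUV into gray levels 1..G.

    The maximum of the range maps to level G.  A constant in-mask signal
    (zero range) maps every voxel to level 1 and is flagged, not an error.
    """
    if n_levels < 2:
        raise DataError(f"n_levels must be >= 2, got {n_levels}")
    x = vol.values[mask.mask].astype(np.float64)
    if value_range is None:
        value_range = (float(x.min()), float(x.max()))
    lo, hi = value_range
    levels = np.zeros(vol.shape, dtype=np.int32)
    if hi <= lo:
        levels[mask.mask] = 1
        return LevelVolume(levels, n_levels, (lo, hi), constant=True)
    binned = np.floor((x - lo) / (hi - lo) * n_levels).astype(np.int32) + 1
    binned = np.clip(binned, 1, n_levels)
    levels[mask.mask] = binned
    return LevelVolume(levels, n_levels, (lo, hi))


def build_glcm(
    lv: LevelVolume,
    offsets: tuple[tuple[int, int, int], ...] | None = None,
    symmetric: bool = True,
) -> GLCMMatrix:
    """Count co-occurring in-mask level pairs over the offset set and normalize."""
    if offsets is None:
        offsets = OFFSETS_3D
    offsets = tuple(tuple(int(v) for v in off) for off in offsets)
    if not offsets:
        raise DataError("at least one offset is required")
    if any(len(off) != 3 or off == (0, 0, 0) for off in offsets):
        raise DataError("offsets must be nonzero 3D integer displacements")
    lev = lv.levels
    G = lv.n_levels
    counts = np.zeros((G, G), dtype=np.float64)
    for off in offsets:
        src, dst = [], []
        for d, n in zip(off, lev.shape):
            if abs(d) >= n:
                src = None
                break
            if d >= 0:
                src.append(slice(0, n - d))
                dst.append(slice(d, n))
            else:
                src.append(slice(-d, n))
                dst.append(slice(0, n + d))
        if src is None:
            continue
        a = lev[tuple(src)]
        b = lev[tuple(dst)]
        valid = (a > 0) & (b > 0)
        np.add.at(counts, (a[valid] - 1, b[valid] - 1), 1.0)
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise DataError("empty GLCM: no valid in-mask voxel pair for any offset")
    return GLCMMatrix(counts / total, offsets, symmetric)


def glcm_features(M: GLCMMatrix) -> TextureFeatures:
    """Contrast, correlation, energy, homogeneity from a normalized GLCM.

    Correlation requires both marginal SDs to be positive; for a constant
    image it is reported as NaN with a reason, the other three still return.
    """
    P = M.P
    G = P.shape[0]
    i = np.arange(1, G + 1, dtype=np.float64)
    II, JJ = np.meshgrid(i, i, indexing="ij")
    contrast = float(((II - JJ) ** 2 * P).sum())
    energy = float((P**2).sum())
    homogeneity = float((P / (1.0 + np.abs(II - JJ))).sum())

    p_i = P.sum(axis=1)
    p_j = P.sum(axis=0)
    mu_i = float((i * p_i).sum())
    mu_j = float((i * p_j).sum())
    var_i = float(((i - mu_i) ** 2 * p_i).sum())
    var_j = float(((i - mu_j) ** 2 * p_j).sum())
    if var_i <= 0 or var_j <= 0:
        correlation = float("nan")
        note = "undefined: zero marginal variance (constant image)"
    else:
        correlation = float(
            (((II - mu_i) * (JJ - mu_j) * P).sum()) / np.sqrt(var_i * var_j)
        )
        note = ""
    return TextureFeatures(
        contrast=contrast,
        correlation=correlation,
        energy=energy,
        homogeneity=homogeneity,
        correlation_note=note,
    )


def texture_pipeline(
    vol: SUVVolume,
    mask: VOIMask,
    n_levels: int = 8,
    mode: str = "3d",
    value_range: tuple[float, float] | None = None,
) -> TextureFeatures:
    """Discretize, build the GLCM for the requested direction mode, and compute features."""
    if mode == "3d":
        offsets = OFFSETS_3D
    elif mode == "2d-axial":
        offsets = OFFSETS_2D_AXIAL
    else:
        raise DataError(f"unknown GLCM mode {mode!r}; expected '3d' or '2d-axial'")
    lv = discretize(vol, mask, n_levels=n_levels, value_range=value_range)
    return glcm_features(build_glcm(lv, offsets=offsets, symmetric=True))
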