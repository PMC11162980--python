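"""Subcortical-ROI texture features: gray-level quantization, gray-level
dependence (GLDM) and size-zone (GLSZM) matrices, first-order statistics,
and correlation-based pruning.

Both matrices follow the standard radiomics definitions with 26-connectivity
in 3D: GLDM counts, per voxel, how many neighbors share its (quantized) gray
level within a tolerance ``alpha``; GLSZM counts connected zones of equal
gray level by their size. Intensities are quantized to a fixed number of
equal-width bins over the ROI's own range, so the features are invariant to
affine intensity rescaling. Entropy-type features use log base 2.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .grids import AtlasLabels, VolumeGrid

__all__ = [
    "QuantizedROI",
    "GLDMatrix",
    "GLSZMatrix",
    "quantize",
    "gldm",
    "glszm",
    "ldhgle",
    "lahgle",
    "gldm_features",
    "glszm_features",
    "first_order_features",
    "extract_roi_textures",
    "prune_correlated",
    "DEFAULT_ROI_NAMES",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)

#: label -> abbreviation for the 16 subcortical ROIs (8 structures x 2 sides)
DEFAULT_ROI_NAMES = {
    i + 1: side + name
    for i, (side, name) in enumerate(
        (s, n)
        for n in ("CAU", "PUT", "THA", "GPi", "GPe", "STN", "SN", "RN")
        for s in ("l", "r")
    )
}


@dataclass
class QuantizedROI:
    """Dense view of one ROI: levels 1..n_levels inside, 0 outside."""

    levels: np.ndarray  # int array over the ROI bounding box
    n_levels: int
    raw: np.ndarray  # raw intensities of in-ROI voxels (flat)
    voxel_volume: float  # mm^3

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.levels))


@dataclass
class GLDMatrix:
    """P[i-1, j-1] = number of voxels at gray level i with dependence size j
    (dependence size = neighbor count + 1)."""

    P: np.ndarray
    Nz: int


@dataclass
class GLSZMatrix:
    """P[i-1, s-1] = number of connected zones of gray level i and size s."""

    P: np.ndarray
    Nz: int


def quantize(
    v: VolumeGrid, atlas: AtlasLabels, roi_id: int, n_levels: int = 32
) -> QuantizedROI:
    """Fixed-bin-count quantization of one ROI into equal-width bins."""
    atlas.check_aligned(v)
    mask = atlas.mask(roi_id)
    if not mask.any():
        raise ValueError(f"ROI {roi_id} is empty")
    idx = np.nonzero(mask)
    lo = [int(a.min()) for a in idx]
    hi = [int(a.max()) + 1 for a in idx]
    box = tuple(slice(a, b) for a, b in zip(lo, hi))
    sub_mask = mask[box]
    sub = v.data[box].astype(np.float64)
    raw = sub[sub_mask]
    vmin, vmax = raw.min(), raw.max()
    levels = np.zeros(sub.shape, dtype=np.int32)
    if vmax == vmin:
        levels[sub_mask] = 1
    else:
        width = (vmax - vmin) / n_levels
        q = np.floor((sub[sub_mask] - vmin) / width).astype(np.int32) + 1
        levels[sub_mask] = np.clip(q, 1, n_levels)
    vv = float(np.prod(v.voxel_size))
    return QuantizedROI(levels=levels, n_levels=n_levels, raw=raw, voxel_volume=vv)


def _neighbor_shifts() -> list[tuple[int, int, int]]:
    return [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]


def gldm(q: QuantizedROI, alpha: int = 0, connectivity: int = 26) -> GLDMatrix:
    """Gray-level dependence matrix with 26-neighborhood.

    A neighbor is dependent when it lies in the ROI and its level differs by
    at most ``alpha``; each voxel contributes one count at (its level,
    dependence count + 1).
    """
    if connectivity != 26:
        raise ValueError("only 26-connectivity is supported")
    lv = np.pad(q.levels, 1)
    inroi = lv > 0
    core = tuple(slice(1, s - 1) for s in lv.shape)
    counts = np.zeros(q.levels.shape, dtype=np.int32)
    for dx, dy, dz in _neighbor_shifts():
        sh = tuple(slice(1 + d, s - 1 + d) for d, s in zip((dx, dy, dz), lv.shape))
        dep = inroi[sh] & (np.abs(lv[sh] - lv[core]) <= alpha)
        counts += dep
    mask = q.levels > 0
    P = np.zeros((q.n_levels, 27), dtype=np.int64)
    np.add.at(P, (q.levels[mask] - 1, counts[mask]), 1)
    return GLDMatrix(P=P, Nz=int(mask.sum()))


def glszm(q: QuantizedROI, connectivity: int = 26) -> GLSZMatrix:
    """Gray-level size-zone matrix: 26-connected components per gray level."""
    if connectivity != 26:
        raise ValueError("only 26-connectivity is supported")
    n_vox = q.n_voxels
    zones: list[tuple[int, int]] = []  # (level, size)
    max_size = 1
    for level in range(1, q.n_levels + 1):
        lab, n = ndimage.label(q.levels == level, structure=_STRUCT26)
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        for s in sizes:
            zones.append((level, int(s)))
            max_size = max(max_size, int(s))
    P = np.zeros((q.n_levels, max_size), dtype=np.int64)
    for level, s in zones:
        P[level - 1, s - 1] += 1
    m = GLSZMatrix(P=P, Nz=len(zones))
    assert int((P * np.arange(1, max_size + 1)[None, :]).sum()) == n_vox
    return m


def _ij(P: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    i = np.arange(1, P.shape[0] + 1, dtype=np.float64)[:, None]
    j = np.arange(1, P.shape[1] + 1, dtype=np.float64)[None, :]
    return i, j


def ldhgle(m: GLDMatrix) -> float:
    """Large-dependence high-gray-level emphasis: sum P*i^2*j^2 / Nz."""
    if m.Nz <= 0:
        raise ValueError("empty dependence matrix")
    i, j = _ij(m.P)
    return float((m.P * i**2 * j**2).sum() / m.Nz)


def lahgle(m: GLSZMatrix) -> float:
    """Large-area high-gray-level emphasis: sum P*i^2*s^2 / Nz."""
    if m.Nz <= 0:
        raise ValueError("empty size-zone matrix")
    i, s = _ij(m.P)
    return float((m.P * i**2 * s**2).sum() / m.Nz)


def _matrix_family(P: np.ndarray, Nz: int, size_word: str, small: str, large: str) -> dict:
    i, j = _ij(P)
    Pn = P / Nz
    pg = Pn.sum(axis=1)  # per gray level
    ps = Pn.sum(axis=0)  # per dependence/size
    mu_i = float((pg * i[:, 0]).sum())
    mu_j = float((ps * j[0, :]).sum())
    ent = -float((Pn[Pn > 0] * np.log2(Pn[Pn > 0])).sum())
    return {
        f"{small}Emphasis": float((Pn / j**2).sum()),
        f"{large}Emphasis": float((Pn * j**2).sum()),
        "GrayLevelNonUniformity": float((P.sum(axis=1) ** 2).sum() / Nz),
        f"{size_word}NonUniformity": float((P.sum(axis=0) ** 2).sum() / Nz),
        "LowGrayLevelEmphasis": float((Pn / i**2).sum()),
        "HighGrayLevelEmphasis": float((Pn * i**2).sum()),
        f"{small}LowGrayLevelEmphasis": float((Pn / (i**2 * j**2)).sum()),
        f"{small}HighGrayLevelEmphasis": float((Pn * i**2 / j**2).sum()),
        f"{large}LowGrayLevelEmphasis": float((Pn * j**2 / i**2).sum()),
        f"{large}HighGrayLevelEmphasis": float((Pn * i**2 * j**2).sum()),
        "GrayLevelVariance": float((Pn * (i - mu_i) ** 2).sum()),
        f"{size_word}Variance": float((Pn * (j - mu_j) ** 2).sum()),
        f"{size_word}Entropy": ent,
    }


def gldm_features(m: GLDMatrix) -> dict[str, float]:
    if m.Nz <= 0:
        raise ValueError("empty dependence matrix")
    return _matrix_family(m.P, m.Nz, "Dependence", "SmallDependence", "LargeDependence")


def glszm_features(m: GLSZMatrix) -> dict[str, float]:
    if m.Nz <= 0:
        raise ValueError("empty size-zone matrix")
    out = _matrix_family(m.P, m.Nz, "SizeZone", "SmallArea", "LargeArea")
    n_vox = int((m.P * np.arange(1, m.P.shape[1] + 1)[None, :]).sum())
    out["ZonePercentage"] = m.Nz / n_vox
    return out


def first_order_features(q: QuantizedROI) -> dict[str, float]:
    """19 first-order statistics of the raw ROI intensities; entropy and
    uniformity use the quantized levels. Moment ratios of a constant ROI are
    defined as 0."""
    x = q.raw
    n = x.size
    var = float(x.var())
    sd = float(np.sqrt(var))
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    lev = q.levels[q.levels > 0]
    p_lev = np.bincount(lev)[1:] / n
    p_lev = p_lev[p_lev > 0]
    return {
        "Energy": float((x**2).sum()),
        "TotalEnergy": float((x**2).sum() * q.voxel_volume),
        "Entropy": -float((p_lev * np.log2(p_lev)).sum()),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(x.mean()),
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - x.mean()).mean()),
        "RobustMeanAbsoluteDeviation": float(np.abs(robust - robust.mean()).mean()),
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "StandardDeviation": sd,
        "Skewness": float(stats.skew(x)) if sd > 0 else 0.0,
        "Kurtosis": float(stats.kurtosis(x, fisher=False)) if sd > 0 else 0.0,
        "Variance": var,
        "Uniformity": float((p_lev**2).sum()),
    }


FAMILY_LABELS = {
    "firstorder": "First Order",
    "gldm": "Gray Level Dependence Matrix",
    "glszm": "Gray Level Size Zone Matrix",
}
DEFAULT_INVENTORY = ("firstorder", "gldm", "glszm")


def extract_roi_textures(
    v: VolumeGrid,
    atlas: AtlasLabels,
    roi_ids: list[int] | None = None,
    inventory: tuple[str, ...] = DEFAULT_INVENTORY,
    n_levels: int = 32,
    roi_names: dict[int, str] | None = None,
) -> pd.Series:
    """Named texture vector over the requested ROIs.

    Names follow "<roi> <family label> <feature>", e.g.
    "rTHA Gray Level Dependence Matrix LargeDependenceHighGrayLevelEmphasis".
    """
    if roi_ids is None:
        roi_ids = atlas.roi_ids
    names = roi_names or atlas.roi_names
    present = set(atlas.roi_ids)
    out: dict[str, float] = {}
    for roi_id in roi_ids:
        if roi_id not in present:
            raise ValueError(f"ROI {roi_id} not present in atlas")
        roi = names.get(roi_id, f"ROI_{roi_id}")
        q = quantize(v, atlas, roi_id, n_levels)
        for family in inventory:
            if family == "firstorder":
                feats = first_order_features(q)
            elif family == "gldm":
                feats = gldm_features(gldm(q))
            elif family == "glszm":
                feats = glszm_features(glszm(q))
            else:
                raise ValueError(f"unknown feature family {family!r}")
            for fname, val in feats.items():
                out[f"{roi} {FAMILY_LABELS[family]} {fname}"] = val
    return pd.Series(out)


def prune_correlated(X: pd.DataFrame, threshold: float = 0.9) -> list[str]:
    """Greedy elimination of highly correlated feature pairs.

    While any pair exceeds |Pearson r| > threshold, take the strongest such
    pair and drop the member with the larger mean absolute correlation to
    all remaining features (ties: drop the later column). Deterministic;
    compute on training records only.
    """
    if len(X) < 3:
        raise ValueError("need at least 3 records to estimate correlations")
    cols = list(X.columns)
    arr = X.to_numpy(dtype=np.float64)
    sd = arr.std(axis=0)
    corr = np.zeros((arr.shape[1], arr.shape[1]))
    ok = sd > 0
    if ok.any():
        sub = np.corrcoef(arr[:, ok], rowvar=False)
        corr[np.ix_(ok, ok)] = np.atleast_2d(sub)
    # constant columns correlate perfectly with each other by convention
    const = ~ok
    corr[np.ix_(const, const)] = 1.0
    np.fill_diagonal(corr, 0.0)
    ac = np.abs(corr)
    alive = np.ones(len(cols), dtype=bool)
    while True:
        sub = np.where(alive[:, None] & alive[None, :], ac, 0.0)
        if sub.max() <= threshold:
            break
        a, b = np.unravel_index(np.argmax(sub), sub.shape)
        a, b = min(a, b), max(a, b)
        mean_a = sub[a, alive].mean()
        mean_b = sub[b, alive].mean()
        drop = b if mean_b >= mean_a else a
        alive[drop] = False
    return [c for c, keep in zip(cols, alive) if keep]
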