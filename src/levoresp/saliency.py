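"""Grad-CAM attribution seeded by the selected deep features.

The selected features (survivors of the selection cascade) are mapped back
through the flatten layer to their (channel, x, y, z) positions in the
post-pool feature map and given their signed RFE importances as gradients;
every excluded position receives a gradient of -0.001. The seed is
backpropagated through the flatten (a reshape) and the max pool (gradient
routed to each cell's argmax) to the last convolutional layer. Channel
weights are the spatial means of these gradients; the map is the rectified
channel-weighted activation sum, max-normalized to [0, 1], trilinearly
upsampled to the input grid, and thresholded (0.4 by default) into
26-connected clusters reported with per-ROI overlap fractions.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .deep import DeepExtractor, feature_to_coords, head_pool_backward
from .grids import AtlasLabels, VolumeGrid
from .selection import SelectionResult

__all__ = [
    "EXCLUDED_GRADIENT",
    "SaliencyMap",
    "ClusterReport",
    "seed_gradients",
    "gradcam",
    "threshold_clusters",
]

#: gradient assigned to features that did not survive selection
EXCLUDED_GRADIENT = -0.001

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class SaliencyMap:
    conv_map: np.ndarray  # heat map at last-conv resolution, >= 0
    upsampled: np.ndarray  # volume-resolution map, max-normalized to [0, 1]
    threshold: float | None = None


@dataclass
class ClusterReport:
    cluster_labels: np.ndarray  # 0 background, 1..n clusters
    sizes: dict[int, int]
    roi_overlap: dict[int, dict[str, float]]  # cluster -> roi name -> fraction
    dominant: int | None  # largest cluster id, None when no voxel passes
    threshold: float


def seed_gradients(
    selection: SelectionResult,
    pooled_shape: tuple[int, int, int, int],
    name_prefix: str = "ResNet",
    use_importances: bool = True,
) -> np.ndarray:
    """Gradient seed over the post-pool feature map.

    Selected features carry their signed RFE importance (or +1.0 when
    ``use_importances`` is off); all other positions carry -0.001. Feature
    names must parse as ``<prefix>_<flat index>`` within the map.
    """
    seed = np.full(pooled_shape, EXCLUDED_GRADIENT, dtype=np.float64)
    n = int(np.prod(pooled_shape))
    for name in selection.names:
        prefix, _, idx_str = name.rpartition("_")
        if prefix != name_prefix or not idx_str.isdigit():
            raise ValueError(f"cannot resolve feature name {name!r} to a flat index")
        idx = int(idx_str)
        if idx >= n:
            raise ValueError(f"feature {name!r} outside the {n}-element map")
        value = selection.importances.get(name, 1.0) if use_importances else 1.0
        seed[feature_to_coords(idx, pooled_shape)] = value
    return seed


def _upsample(map3d: np.ndarray, target_shape: tuple[int, int, int]) -> np.ndarray:
    """Trilinear upsampling to an exact target shape."""
    coords = np.meshgrid(
        *[np.linspace(0, s - 1, t) for s, t in zip(map3d.shape, target_shape)],
        indexing="ij",
    )
    return ndimage.map_coordinates(map3d, np.stack(coords), order=1, mode="nearest")


def gradcam(
    extractor: DeepExtractor, volume: VolumeGrid | np.ndarray, seed: np.ndarray
) -> SaliencyMap:
    """Backpropagate the seed to the last conv layer and form the heat map.

    map = relu(sum_c w_c * A_c) with w_c the spatial mean of the gradient in
    channel c; the volume-resolution map is max-normalized to [0, 1].
    """
    features, conv, arg = extractor.forward(volume)
    pooled_shape = (conv.shape[0],) + arg.shape[1:]
    if tuple(seed.shape) != pooled_shape:
        raise ValueError(
            f"seed shape {seed.shape} does not match pooled map {pooled_shape}"
        )
    grad = head_pool_backward(
        seed, arg, extractor.config.pool_kernel, conv.shape
    )  # (C, X, Y, Z) at last-conv resolution
    weights = grad.mean(axis=(1, 2, 3))
    cam = np.maximum((weights[:, None, None, None] * conv).sum(axis=0), 0.0)
    data = volume.data if isinstance(volume, VolumeGrid) else np.asarray(volume)
    up = _upsample(cam, data.shape)
    up = np.maximum(up, 0.0)
    peak = up.max()
    if peak > 0:
        up = up / peak
    return SaliencyMap(conv_map=cam, upsampled=up)


def cohort_average_map(maps: list[SaliencyMap]) -> SaliencyMap:
    """Average of per-subject normalized maps, re-normalized to [0, 1]."""
    if not maps:
        raise ValueError("no maps to average")
    avg = np.mean([m.upsampled for m in maps], axis=0)
    conv = np.mean([m.conv_map for m in maps], axis=0)
    peak = avg.max()
    if peak > 0:
        avg = avg / peak
    return SaliencyMap(conv_map=conv, upsampled=avg)


def threshold_clusters(
    smap: SaliencyMap, atlas: AtlasLabels, threshold: float = 0.4
) -> ClusterReport:
    """26-connected clusters of the normalized map at/above the threshold.

    Per cluster, the overlap fraction with each atlas ROI is
    |cluster ∩ ROI| / |ROI|; the dominant cluster is the largest (ties: the
    smaller label id).
    """
    binary = smap.upsampled >= threshold
    labels, n = ndimage.label(binary, structure=_STRUCT26)
    sizes = {i: int((labels == i).sum()) for i in range(1, n + 1)}
    overlap: dict[int, dict[str, float]] = {}
    for ci in range(1, n + 1):
        cmask = labels == ci
        per_roi: dict[str, float] = {}
        for roi_id in atlas.roi_ids:
            rmask = atlas.mask(roi_id)
            frac = float((cmask & rmask).sum() / rmask.sum())
            if frac > 0:
                per_roi[atlas.name_of(roi_id)] = frac
        overlap[ci] = per_roi
    dominant = max(sizes, key=lambda i: (sizes[i], -i)) if sizes else None
    return ClusterReport(labels, sizes, overlap, dominant, threshold)
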