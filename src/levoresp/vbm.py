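"""Age-corrected gray-matter-intensity features (the VBM-style branch).

Input volumes are treated as already registered, modulated gray-matter-like
maps on a common grid. The branch: 8 mm FWHM Gaussian smoothing ->
healthy-control per-voxel age regression and correction -> voxelwise Welch
t-test between responder classes on the training set to build a
discriminative-voxel mask -> PCA to the first 50 components. All fitting
(age model, mask, PCA mean/loadings) uses training or healthy-control data
only; test records are projected with the frozen state.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from sklearn.decomposition import PCA

from .grids import VolumeGrid

__all__ = [
    "AgeModel",
    "DiscriminativeMask",
    "smooth_volume",
    "fit_age_model",
    "age_correct",
    "find_discriminative_voxels",
    "pca_reduce",
    "GrayMatterIntensityExtractor",
]

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class AgeModel:
    """Per-voxel linear intensity-on-age fit from healthy controls."""

    slope: np.ndarray  # intensity / year
    intercept: np.ndarray
    reference_age: float


@dataclass
class DiscriminativeMask:
    mask: np.ndarray  # boolean
    alpha: float
    statistic: str = "welch_t"


def smooth_volume(v: VolumeGrid, fwhm_mm: float = 8.0) -> VolumeGrid:
    """Gaussian smoothing with the kernel width given as FWHM in mm.

    sigma (voxels) = fwhm / (voxel_size * 2*sqrt(2 ln 2)) per axis; reflect
    padding preserves the mean of constant images. fwhm 0 is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError(f"fwhm must be >= 0, got {fwhm_mm}")
    if fwhm_mm == 0:
        return VolumeGrid(v.data.copy(), v.voxel_size, v.orientation)
    sigmas = [fwhm_mm / (vs * FWHM_TO_SIGMA) for vs in v.voxel_size]
    out = ndimage.gaussian_filter(v.data.astype(np.float64), sigma=sigmas, mode="reflect")
    return VolumeGrid(out, v.voxel_size, v.orientation)


def _stack(volumes: list[VolumeGrid]) -> np.ndarray:
    shapes = {v.shape for v in volumes}
    if len(shapes) != 1:
        raise ValueError(f"volumes have mixed shapes: {sorted(shapes)}")
    return np.stack([v.data for v in volumes]).astype(np.float64)


def fit_age_model(healthy_volumes: list[VolumeGrid], ages: np.ndarray) -> AgeModel:
    """Per-voxel ordinary least squares of intensity on age."""
    ages = np.asarray(ages, dtype=float)
    if len(healthy_volumes) < 10:
        raise ValueError("need at least 10 healthy controls")
    if len(healthy_volumes) != len(ages):
        raise ValueError("one age per volume required")
    var = ages.var()
    if var <= 0:
        raise ValueError("age variance must be positive")
    X = _stack(healthy_volumes)  # (n, x, y, z)
    a = ages - ages.mean()
    slope = np.tensordot(a, X - X.mean(axis=0), axes=(0, 0)) / (var * len(ages))
    intercept = X.mean(axis=0) - slope * ages.mean()
    return AgeModel(slope=slope, intercept=intercept, reference_age=float(ages.mean()))


def age_correct(v: VolumeGrid, age: float, model: AgeModel) -> VolumeGrid:
    """Remove the healthy-aging trend: v - slope * (age - reference_age)."""
    if model.slope.shape != v.shape:
        raise ValueError(
            f"age model grid {model.slope.shape} does not match volume {v.shape}"
        )
    out = v.data - model.slope * (age - model.reference_age)
    return VolumeGrid(out, v.voxel_size, v.orientation)


def find_discriminative_voxels(
    train_volumes: list[VolumeGrid], labels: np.ndarray, alpha: float = 0.001
) -> DiscriminativeMask:
    """Voxelwise two-sample Welch t-test; keep voxels with p < alpha.

    Fitted on training data only; ``labels`` is the binary responder class.
    """
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both responder classes must be present")
    X = _stack(train_volumes)
    res = stats.ttest_ind(X[y == 1], X[y == 0], axis=0, equal_var=False)
    pvals = np.asarray(res.pvalue)
    mask = np.nan_to_num(pvals, nan=1.0) < alpha
    return DiscriminativeMask(mask=mask, alpha=alpha)


def pca_reduce(
    X: np.ndarray, n_components: int = 50
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centered PCA keeping the first min(n_components, rank) components.

    Returns (scores, loadings, mean); the deterministic sign convention makes
    the largest-magnitude loading of each component positive so repeated fits
    agree. Project new rows as (X_new - mean) @ loadings.T.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2D matrix with at least 2 records")
    if X.shape[1] == 0:
        raise ValueError("empty feature matrix (mask selected no voxels?)")
    k = min(n_components, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=k, svd_solver="auto", random_state=0)
    scores = pca.fit_transform(X)
    loadings = pca.components_
    flip = np.sign(loadings[np.arange(k), np.argmax(np.abs(loadings), axis=1)])
    flip[flip == 0] = 1.0
    return scores * flip[None, :], loadings * flip[:, None], pca.mean_


@dataclass
class GrayMatterIntensityExtractor:
    """Frozen-state wrapper tying the branch together.

    ``fit`` consumes healthy controls and labeled training volumes;
    ``transform`` maps any volume list to the PCA feature space using only
    the fitted state.
    """

    fwhm_mm: float = 8.0
    alpha: float = 0.001
    n_components: int = 50

    def fit(
        self,
        train_volumes: list[VolumeGrid],
        train_ages: np.ndarray,
        train_labels: np.ndarray,
        healthy_volumes: list[VolumeGrid],
        healthy_ages: np.ndarray,
    ) -> "GrayMatterIntensityExtractor":
        smoothed_h = [smooth_volume(v, self.fwhm_mm) for v in healthy_volumes]
        self.age_model_ = fit_age_model(smoothed_h, healthy_ages)
        corrected = self._preprocess(train_volumes, train_ages)
        self.mask_ = find_discriminative_voxels(corrected, train_labels, self.alpha)
        M = _stack(corrected)[:, self.mask_.mask]
        if M.shape[1] == 0:
            raise ValueError(f"no voxel passed the alpha={self.alpha} mask")
        scores, self.loadings_, self.mean_ = pca_reduce(M, self.n_components)
        self.feature_names_ = [f"PCA_{i + 1}" for i in range(scores.shape[1])]
        return self

    def _preprocess(self, volumes: list[VolumeGrid], ages: np.ndarray) -> list[VolumeGrid]:
        return [
            age_correct(smooth_volume(v, self.fwhm_mm), a, self.age_model_)
            for v, a in zip(volumes, ages)
        ]

    def transform(self, volumes: list[VolumeGrid], ages: np.ndarray) -> np.ndarray:
        corrected = self._preprocess(volumes, ages)
        M = _stack(corrected)[:, self.mask_.mask]
        return (M - self.mean_) @ self.loadings_.T
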