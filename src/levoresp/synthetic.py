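"""Synthetic cohorts: atlas-labeled 3D volumes plus clinical tables with a
planted, configurable class structure.

The generator emulates the statistical skeleton of a levodopa-challenge
cohort: registered T1-like volumes on a shared grid with an integer ROI
atlas, a global age->intensity trend, class-dependent intensity and texture
effects planted in designated ROIs, and clinical covariates whose marginal
moments match the study's training-set demographics (age 64.12 +/- 9.22 y,
disease duration 41.88 +/- 21.61 months, LEDD 645.40 +/- 426.97 mg/day,
MDS-UPDRS III OFF 27.51 +/- 12.38). It makes no attempt at anatomy: ROIs
are axis-aligned boxes and the background is a smooth random field.

All randomness flows from one master seed through named substreams (one per
record), so generating more records never perturbs earlier ones.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .cohort import ClinicalRecord, GOOD, BAD, classify_response, improvement_rate
from .grids import AtlasLabels, VolumeGrid

__all__ = [
    "ClinicalMoments",
    "SyntheticConfig",
    "SyntheticCohort",
    "generate_atlas",
    "generate_cohort",
    "generate_healthy",
    "planted_feature_matrix",
]

#: per-voxel measurement noise (intensity units); effect sizes are in units of this
NOISE_SD = 10.0
#: baseline mean tissue intensity
BASELINE = 100.0
#: age the global trend is anchored at
AGE_ANCHOR = 60.0

# fixed substream tags (spawn keys of the master SeedSequence)
_ATLAS, _BASE, _CLIN, _VOL, _HEALTHY = 0, 1, 2, 3, 4


def _stream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


@dataclass(frozen=True)
class ClinicalMoments:
    """Mean/sd of the clinical covariates (training-cohort defaults)."""

    age: tuple[float, float] = (64.12, 9.22)
    duration_months: tuple[float, float] = (41.88, 21.61)
    ledd: tuple[float, float] = (645.40, 426.97)
    updrs3_off: tuple[float, float] = (27.51, 12.38)
    male_fraction: float = 116 / 173


@dataclass
class SyntheticConfig:
    n_patients: int = 73
    records_per_patient: int = 3
    volume_shape: tuple[int, int, int] = (48, 56, 48)
    voxel_size_mm: float = 3.0
    n_rois: int = 16
    signal_roi_ids: tuple[int, ...] = (7,)
    intensity_effect: float = 0.0  # standardized mean shift d inside signal ROIs (good class)
    texture_effect: float = 1.0  # within-ROI noise variance ratio (good class), >= 1
    age_slope: float = 0.0  # intensity units per year, applied globally
    good_fraction: float = 0.5
    clinical_link: float = 0.5  # class separation (in sd units) of duration/LEDD/OFF
    clinical_moments: ClinicalMoments = field(default_factory=ClinicalMoments)
    n_healthy: int = 100
    good_rate_range: tuple[float, float] = (35.0, 70.0)
    bad_rate_range: tuple[float, float] = (-10.0, 25.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.good_fraction < 1:
            raise ValueError("good_fraction must be in (0, 1)")
        if self.texture_effect < 1:
            raise ValueError("texture_effect is a variance ratio >= 1")
        bad_ids = set(self.signal_roi_ids) - set(range(1, self.n_rois + 1))
        if bad_ids:
            raise ValueError(f"signal_roi_ids {sorted(bad_ids)} outside 1..{self.n_rois}")

    @property
    def n_records(self) -> int:
        return self.n_patients * self.records_per_patient

    def to_dict(self) -> dict:
        d = asdict(self)
        d["clinical_moments"] = asdict(self.clinical_moments)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "clinical_moments" in d and isinstance(d["clinical_moments"], dict):
            cm = {
                k: tuple(v) if isinstance(v, (list, tuple)) else v
                for k, v in d["clinical_moments"].items()
            }
            d["clinical_moments"] = ClinicalMoments(**cm)
        for k in ("volume_shape", "signal_roi_ids", "good_rate_range", "bad_rate_range"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class SyntheticCohort:
    volumes: list[VolumeGrid]
    atlas: AtlasLabels
    clinical: list[ClinicalRecord]
    truth_class: list[str]
    healthy_volumes: list[VolumeGrid]
    healthy_ages: np.ndarray
    config: SyntheticConfig

    @property
    def y(self) -> np.ndarray:
        """Binary labels, good responder = 1."""
        return np.array([1 if c == GOOD else 0 for c in self.truth_class])


def generate_atlas(
    volume_shape: tuple[int, int, int], n_rois: int, seed: int = 0
) -> AtlasLabels:
    """Disjoint axis-aligned box ROIs labeled 1..n_rois on a background of 0.

    The volume is tiled into cells with a one-voxel gap; a seeded shuffle
    picks which cells host ROIs, so any two ROIs are separated and each
    holds at least 27 voxels.
    """
    if n_rois < 2:
        raise ValueError("need at least 2 ROIs")
    shape = tuple(int(s) for s in volume_shape)
    cell = 8  # cell edge; hosts a box of up to cell-2 per axis
    grid = tuple(s // cell for s in shape)
    capacity = int(np.prod(grid))
    if capacity < n_rois:
        raise ValueError(
            f"shape {shape} fits only {capacity} ROI cells of edge {cell}; "
            f"{n_rois} requested"
        )
    rng = _stream(seed, _ATLAS)
    cells = [(i, j, k) for i in range(grid[0]) for j in range(grid[1]) for k in range(grid[2])]
    idx = rng.permutation(len(cells))[:n_rois]
    labels = np.zeros(shape, dtype=np.int32)
    for label, ci in enumerate(idx, start=1):
        i, j, k = cells[ci]
        # random box of edge 3..cell-2 inside the cell, 1-voxel margin
        edges = rng.integers(3, cell - 1, size=3)
        offs = [rng.integers(1, cell - 1 - e + 1) for e in edges]
        sl = tuple(
            slice(o * cell + off, o * cell + off + e)
            for o, off, e in zip((i, j, k), offs, edges)
        )
        labels[sl] = label
    return AtlasLabels(labels)


def _baseline_field(shape: tuple[int, int, int], seed: int) -> np.ndarray:
    rng = _stream(seed, _BASE)
    field_ = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=4.0)
    field_ *= 5.0 / max(field_.std(), 1e-12)
    return (BASELINE + field_).astype(np.float32)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    var_ratio = 1.0 + (sd / mean) ** 2
    return np.log(mean / np.sqrt(var_ratio)), np.sqrt(np.log(var_ratio))


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, low: float) -> float:
    """Rejection sampling; exact for the mild truncations used here."""
    while True:
        x = rng.normal(mean, sd)
        if x >= low:
            return float(x)


def _render_volume(
    rng: np.random.Generator,
    baseline: np.ndarray,
    atlas: AtlasLabels,
    cfg: SyntheticConfig,
    age: float,
    good: bool,
) -> VolumeGrid:
    vol = baseline + cfg.age_slope * (age - AGE_ANCHOR)
    noise = rng.normal(0.0, NOISE_SD, size=baseline.shape)
    if good and cfg.signal_roi_ids:
        sig = np.isin(atlas.labels, cfg.signal_roi_ids)
        if cfg.intensity_effect != 0.0:
            vol = vol + cfg.intensity_effect * NOISE_SD * sig
        if cfg.texture_effect > 1.0:
            noise[sig] *= np.sqrt(cfg.texture_effect)
    vs = (cfg.voxel_size_mm,) * 3
    return VolumeGrid((vol + noise).astype(np.float32), vs)


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Generate a full labeled cohort plus its healthy calibration set."""
    cfg = config
    atlas = generate_atlas(cfg.volume_shape, cfg.n_rois, cfg.seed)
    from .texture import DEFAULT_ROI_NAMES

    names = DEFAULT_ROI_NAMES if cfg.n_rois == 16 else {}
    atlas = AtlasLabels(atlas.labels, (cfg.voxel_size_mm,) * 3, dict(names))
    baseline = _baseline_field(cfg.volume_shape, cfg.seed)
    m = cfg.clinical_moments

    volumes: list[VolumeGrid] = []
    clinical: list[ClinicalRecord] = []
    truth: list[str] = []
    rec_i = 0
    for p in range(cfg.n_patients):
        subject = f"P{p:04d}"
        for v in range(cfg.records_per_patient):
            rng = _stream(cfg.seed, _CLIN, rec_i)
            good = rng.random() < cfg.good_fraction
            half = cfg.clinical_link / 2.0
            sgn = -1.0 if good else 1.0  # good: shorter duration, lower LEDD, higher OFF
            age = rng.normal(m.age[0], m.age[1]) + v  # visits a year apart
            mu_d, s_d = _lognormal_params(*m.duration_months)
            duration = max(rng.lognormal(mu_d, s_d) + sgn * half * m.duration_months[1], 0.0)
            mu_l, s_l = _lognormal_params(*m.ledd)
            ledd = max(rng.lognormal(mu_l, s_l) + sgn * half * m.ledd[1], 0.0)
            off = _truncated_normal(rng, m.updrs3_off[0] - sgn * half * m.updrs3_off[1],
                                    m.updrs3_off[1], 5.0)
            lo, hi = cfg.good_rate_range if good else cfg.bad_rate_range
            rate = rng.uniform(lo, hi)
            on = max(off * (1.0 - rate / 100.0), 0.0)
            sex = "M" if rng.random() < m.male_fraction else "F"
            clinical.append(
                ClinicalRecord(subject, f"V{v:02d}", age, sex, duration, ledd, off, on)
            )
            truth.append(classify_response(improvement_rate(off, on)))
            vrng = _stream(cfg.seed, _VOL, rec_i)
            volumes.append(_render_volume(vrng, baseline, atlas, cfg, age, good))
            rec_i += 1

    healthy_volumes, healthy_ages = generate_healthy(cfg, atlas=atlas, baseline=baseline)
    return SyntheticCohort(volumes, atlas, clinical, truth, healthy_volumes, healthy_ages, cfg)


def generate_healthy(
    config: SyntheticConfig,
    atlas: AtlasLabels | None = None,
    baseline: np.ndarray | None = None,
) -> tuple[list[VolumeGrid], np.ndarray]:
    """Healthy calibration volumes: same age trend, no class effects.

    Ages are drawn uniformly over 45-80 years so the age regression is well
    conditioned.
    """
    cfg = config
    if cfg.n_healthy < 10:
        raise ValueError("need at least 10 healthy controls")
    if atlas is None:
        atlas = generate_atlas(cfg.volume_shape, cfg.n_rois, cfg.seed)
    if baseline is None:
        baseline = _baseline_field(cfg.volume_shape, cfg.seed)
    volumes: list[VolumeGrid] = []
    ages = np.empty(cfg.n_healthy)
    for i in range(cfg.n_healthy):
        rng = _stream(cfg.seed, _HEALTHY, i)
        ages[i] = rng.uniform(45.0, 80.0)
        volumes.append(_render_volume(rng, baseline, atlas, cfg, ages[i], good=False))
    return volumes, ages


def planted_feature_matrix(
    n: int,
    p: int,
    n_informative: int = 5,
    effect: float = 1.5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Tabular benchmark for the selection cascade: standard-normal noise
    features with ``n_informative`` columns shifted by ``effect`` for class 1.

    Returns (X, y, names); informative columns are the first
    ``n_informative`` names, ``signal_0..``, the rest ``noise_*``.
    """
    rng = np.random.default_rng(seed)
    y = (rng.random(n) < 0.5).astype(int)
    X = rng.standard_normal((n, p))
    X[:, :n_informative] += effect * y[:, None]
    names = [f"signal_{i}" for i in range(n_informative)] + [
        f"noise_{i}" for i in range(p - n_informative)
    ]
    return X, y, names
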