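"""End-to-end experiment plumbing.

Ties the stages together the way the study design prescribes: a
participant-grouped 8:2 split; imaging features fitted on training records
only (age model from healthy controls, discriminative mask, PCA, correlation
pruning); the selection cascade on the training features; min-max scaling
fitted on training rows; classifiers tuned by seeded CV; and a frozen
validation mode that applies every fitted artifact to a new cohort with
zero additional fitting (checkable by hashing the fitted state).
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import modeling
from .cohort import ClinicalRecord, CohortSplit, grouped_split
from .deep import DeepExtractor, ExtractorConfig
from .grids import AtlasLabels, VolumeGrid
from .morphgraph import build_network, graph_feature_vector
from .selection import SelectionConfig, SelectionResult, run_sequential
from .synthetic import SyntheticCohort
from .texture import extract_roi_textures, prune_correlated
from .vbm import GrayMatterIntensityExtractor

__all__ = [
    "clinical_frame",
    "ImagingExtractor",
    "FrozenPipeline",
    "run_ablation_on_cohort",
    "repeated_ablation",
    "state_hash",
]

IMAGING_METHODS = ("gmi", "texture", "morphgraph", "deep")


def clinical_frame(records: list[ClinicalRecord]) -> pd.DataFrame:
    """Numeric clinical feature matrix (sex encoded M=1, F=0)."""
    return pd.DataFrame(
        {
            "age": [r.age for r in records],
            "sex": [1.0 if r.sex == "M" else 0.0 for r in records],
            "disease_duration": [r.disease_duration for r in records],
            "ledd": [0.0 if r.ledd is None else r.ledd for r in records],
            "updrs3_off": [r.updrs3_off for r in records],
        }
    )


def state_hash(items) -> str:
    """Deterministic digest of fitted state; (name, value) pairs where the
    value is an ndarray, scalar, string, or a list/dict of those."""
    h = hashlib.sha256()

    def feed(x) -> None:
        if isinstance(x, np.ndarray):
            h.update(str(x.dtype).encode() + str(x.shape).encode())
            h.update(np.ascontiguousarray(x).tobytes())
        elif isinstance(x, dict):
            for k in sorted(x):
                h.update(str(k).encode())
                feed(x[k])
        elif isinstance(x, (list, tuple)):
            for el in x:
                feed(el)
        else:
            h.update(repr(x).encode())

    for name, value in items:
        h.update(str(name).encode())
        feed(value)
    return h.hexdigest()


class ImagingExtractor:
    """Uniform fit/transform facade over the four imaging feature branches."""

    def __init__(self, method: str, atlas: AtlasLabels | None = None, **kwargs):
        if method not in IMAGING_METHODS:
            raise ValueError(f"method must be one of {IMAGING_METHODS}")
        self.method = method
        self.atlas = atlas
        self.kwargs = kwargs
        if method == "deep":
            cfg = kwargs.get("extractor_config") or ExtractorConfig(
                backbone="tiny-cnn", seed=kwargs.get("seed", 0)
            )
            if isinstance(cfg, dict):
                cfg = ExtractorConfig(**cfg)
            self._deep = DeepExtractor(cfg)

    def fit(
        self,
        volumes: list[VolumeGrid],
        ages: np.ndarray,
        labels: np.ndarray,
        healthy_volumes: list[VolumeGrid] | None = None,
        healthy_ages: np.ndarray | None = None,
    ) -> "ImagingExtractor":
        if self.method == "gmi":
            if healthy_volumes is None:
                raise ValueError("gmi needs healthy controls for age correction")
            self._gmi = GrayMatterIntensityExtractor(
                fwhm_mm=self.kwargs.get("fwhm_mm", 8.0),
                alpha=self.kwargs.get("alpha", 0.001),
                n_components=self.kwargs.get("n_components", 50),
            ).fit(volumes, ages, labels, healthy_volumes, healthy_ages)
        elif self.method == "texture":
            train = self._texture_frame(volumes)
            self._retained = prune_correlated(
                train, self.kwargs.get("corr_threshold", 0.9)
            )
        # morphgraph and deep have no trainable state
        return self

    def _texture_frame(self, volumes: list[VolumeGrid]) -> pd.DataFrame:
        rows = [
            extract_roi_textures(
                v, self.atlas, n_levels=self.kwargs.get("n_levels", 32)
            )
            for v in volumes
        ]
        return pd.DataFrame(rows).reset_index(drop=True)

    def transform(self, volumes: list[VolumeGrid], ages: np.ndarray) -> pd.DataFrame:
        if self.method == "gmi":
            scores = self._gmi.transform(volumes, ages)
            return pd.DataFrame(scores, columns=self._gmi.feature_names_)
        if self.method == "texture":
            return self._texture_frame(volumes)[self._retained]
        if self.method == "morphgraph":
            rows = [
                graph_feature_vector(
                    build_network(v, self.atlas, n_bins=self.kwargs.get("n_bins", 64))
                )
                for v in volumes
            ]
            return pd.DataFrame(rows).reset_index(drop=True)
        shape = volumes[0].shape
        names = self._deep.feature_names(shape)
        rows = [self._deep.extract(v) for v in volumes]
        return pd.DataFrame(np.stack(rows), columns=names)

    def state_items(self):
        yield "method", self.method
        if self.method == "gmi" and hasattr(self, "_gmi"):
            g = self._gmi
            yield "age_slope", g.age_model_.slope
            yield "age_intercept", g.age_model_.intercept
            yield "reference_age", g.age_model_.reference_age
            yield "mask", g.mask_.mask
            yield "pca_mean", g.mean_
            yield "pca_loadings", g.loadings_
        elif self.method == "texture" and hasattr(self, "_retained"):
            yield "retained", list(self._retained)
        elif self.method == "deep":
            for k in sorted(self._deep.weights):
                yield f"w.{k}", self._deep.weights[k]


@dataclass
class FrozenPipeline:
    """Every fitted artifact needed to score a new cohort with zero fitting."""

    extractor: ImagingExtractor
    selection: SelectionResult | None
    scalers: dict[str, modeling.ScalerState]
    models: dict[str, object]  # feature_set -> fitted classifier
    feature_columns: dict[str, list[str]]

    def state_hash(self) -> str:
        items = list(self.extractor.state_items())
        if self.selection is not None:
            items.append(("selection", list(self.selection.names)))
            items.append(("importances", dict(self.selection.importances)))
        for name, sc in sorted(self.scalers.items()):
            items.append((f"scaler.{name}.min", sc.col_min))
            items.append((f"scaler.{name}.max", sc.col_max))
        for name, model in sorted(self.models.items()):
            params = model.get_params()
            items.append((f"model.{name}.params", {k: repr(v) for k, v in params.items()}))
        return state_hash(items)

    def predict(
        self,
        volumes: list[VolumeGrid],
        ages: np.ndarray,
        records: list[ClinicalRecord],
        y: np.ndarray,
    ) -> dict[str, float]:
        """Score a new cohort; performs no fitting of any kind."""
        imaging = self.extractor.transform(volumes, ages)
        if self.selection is not None:
            imaging = imaging[self.selection.names]
        clin = clinical_frame(records)
        frames = {
            "imaging": imaging,
            "clinical": clin,
            "union": pd.concat(
                [imaging.reset_index(drop=True), clin.reset_index(drop=True)], axis=1
            ),
        }
        out = {}
        for name, model in self.models.items():
            X = frames[name][self.feature_columns[name]]
            Xs = modeling.minmax_apply(self.scalers[name], X)
            s = modeling._scores(model, Xs)
            out[name] = modeling.micro_auc(y, s)
        return out


def _cohort_indices(cohort: SyntheticCohort, split: CohortSplit):
    keys = [r.key for r in cohort.clinical]
    tr = [i for i, k in enumerate(keys) if k in split.train_ids]
    te = [i for i, k in enumerate(keys) if k in split.test_ids]
    return tr, te


def build_feature_sets(
    cohort: SyntheticCohort,
    split: CohortSplit,
    method: str = "gmi",
    select: bool = True,
    selection_config: SelectionConfig | None = None,
    **extractor_kwargs,
):
    """Extract per-split features with training-only fitting.

    Returns (feature_sets, y_train, y_test, extractor, selection) where
    feature_sets feeds :func:`levoresp.modeling.ablation_experiment`.
    """
    tr, te = _cohort_indices(cohort, split)
    ages = np.array([r.age for r in cohort.clinical])
    y = cohort.y
    vols = cohort.volumes
    ext = ImagingExtractor(method, atlas=cohort.atlas, **extractor_kwargs)
    ext.fit(
        [vols[i] for i in tr],
        ages[tr],
        y[tr],
        healthy_volumes=cohort.healthy_volumes,
        healthy_ages=cohort.healthy_ages,
    )
    img_tr = ext.transform([vols[i] for i in tr], ages[tr])
    img_te = ext.transform([vols[i] for i in te], ages[te])
    selection = None
    if select:
        cfg = selection_config or SelectionConfig(n_repeats=3)
        selection = run_sequential(img_tr, y[tr], cfg)
        if selection.names:
            img_tr = img_tr[selection.names]
            img_te = img_te[selection.names]
    clin = clinical_frame(cohort.clinical)
    clin_tr = clin.iloc[tr].reset_index(drop=True)
    clin_te = clin.iloc[te].reset_index(drop=True)
    img_tr = img_tr.reset_index(drop=True)
    img_te = img_te.reset_index(drop=True)
    feature_sets = {
        "imaging": (img_tr, img_te),
        "clinical": (clin_tr, clin_te),
        "union": (
            pd.concat([img_tr, clin_tr], axis=1),
            pd.concat([img_te, clin_te], axis=1),
        ),
    }
    return feature_sets, y[tr], y[te], ext, selection


def run_ablation_on_cohort(
    cohort: SyntheticCohort,
    method: str = "gmi",
    models: tuple[str, ...] = ("svm",),
    n_seeds: int = 10,
    seed0: int = 0,
    split_seed: int = 0,
    ratio: float = 0.8,
    select: bool = True,
    selection_config: SelectionConfig | None = None,
    **extractor_kwargs,
):
    """One full ablation experiment on a cohort; returns (results, summary)."""
    split = grouped_split(cohort.clinical, ratio=ratio, seed=split_seed)
    feature_sets, y_tr, y_te, _, _ = build_feature_sets(
        cohort, split, method, select, selection_config, **extractor_kwargs
    )
    return modeling.ablation_experiment(
        feature_sets, y_tr, y_te, models=models, n_seeds=n_seeds, seed0=seed0
    )


def repeated_ablation(
    make_cohort,
    n_runs: int = 10,
    base_seed: int = 0,
    method: str = "gmi",
    model: str = "svm",
    select: bool = True,
    selection_config: SelectionConfig | None = None,
    **extractor_kwargs,
) -> pd.DataFrame:
    """Repeat the full experiment over independent run seeds.

    ``make_cohort(seed)`` builds the cohort for one run; each run reseeds
    the generator, the split, and the model CV. Returns one row per
    (run, feature set) with the test AUC.
    """
    rows = []
    for r in range(n_runs):
        seed = base_seed + r
        cohort = make_cohort(seed)
        results, _ = run_ablation_on_cohort(
            cohort,
            method=method,
            models=(model,),
            n_seeds=1,
            seed0=seed,
            split_seed=seed,
            select=select,
            selection_config=selection_config,
            **extractor_kwargs,
        )
        for _, row in results.iterrows():
            rows.append(
                {"run": r, "feature_set": row.feature_set, "auc": row.auc}
            )
    return pd.DataFrame(rows)


def fit_frozen_pipeline(
    cohort: SyntheticCohort,
    split: CohortSplit,
    method: str = "gmi",
    model_kind: str = "svm",
    seed: int = 0,
    select: bool = True,
    selection_config: SelectionConfig | None = None,
    **extractor_kwargs,
) -> FrozenPipeline:
    """Train the full pipeline once and freeze every fitted artifact."""
    feature_sets, y_tr, _, ext, selection = build_feature_sets(
        cohort, split, method, select, selection_config, **extractor_kwargs
    )
    scalers, models, columns = {}, {}, {}
    for name, (Xtr, _) in feature_sets.items():
        scalers[name] = modeling.minmax_fit(Xtr)
        models[name] = modeling.fit_model(
            model_kind, modeling.minmax_apply(scalers[name], Xtr), y_tr, seed
        )
        columns[name] = list(Xtr.columns)
    return FrozenPipeline(ext, selection, scalers, models, columns)
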